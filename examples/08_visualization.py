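"""Manhattan, QQ and CpG-density plots from an association scan.

Writes the three standard figures into ./plots_out and prints the
genomic inflation factor lambda (≈1 for a calibrated scan).
"""

from pathlib import Path

import ewaskit as ek
from ewaskit.plots import PlotConfig

outdir = Path("plots_out")
outdir.mkdir(exist_ok=True)

matrix, sheet, annotation, _ = ek.simulate_ewas_dataset(
    n_samples=100, n_probes=3000, n_causal=30, effect_size=0.5, seed=8
)
spec = ek.ModelSpec(model="glm", exposure="exposure", covariates=["age", "sex"])
table = ek.run_dmp(matrix, sheet, spec, annotation)

ek.manhattan_plot(table, outdir / "manhattan.png")
ek.manhattan_plot(table, outdir / "manhattan_circular.png", PlotConfig(layout="circular"))
_, lam = ek.qq_plot(table, outdir / "qq.png")
ek.cpg_density_plot(annotation, outdir / "density.png", window_bp=1_000_000)

print(f"genomic inflation lambda = {lam:.3f}")
print("wrote:", ", ".join(p.name for p in sorted(outdir.iterdir())))
# lambda slightly above 1 is expected here: 1% of probes carry real signal.
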