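"""Generate the synthetic two-sample study at the scale of the real one.

Builds a study-scale exposure GWAS (~1000 candidate loci, of which ~840
survive genome-wide significance and LD clumping, mean F ≈ 70) and seven
outcome GWAS — four vascular-brain-injury phenotypes carrying a true
protective blood-pressure effect (log-OR 0.035 per mm Hg, OR ≈ 0.70 per
10 mm Hg lower SBP) and three Alzheimer-pathology phenotypes with no effect.

Writes the full summary-statistics bundle under scratch/sim_study/ (large,
regenerable) and the instrument manifest under results/.
"""

import json
from pathlib import Path

from bpmr.simulate import STUDY_OUTCOMES, simulate_study_mimic
from bpmr.sumstats import write_ld, write_sumstats

SEED = 20240917
THETA_VBI = 0.035  # log-OR per mm Hg higher SBP on vascular outcomes

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    outcomes = [(lbl, cat, THETA_VBI if cat == "VBI" else 0.0)
                for lbl, cat, _, _ in STUDY_OUTCOMES]
    bundle = simulate_study_mimic(seed=SEED, outcomes_spec=outcomes)

    out = ROOT / "scratch" / "sim_study"
    out.mkdir(parents=True, exist_ok=True)
    write_sumstats(bundle["exposure"], out / "exposure.tsv")
    for label, stats in bundle["outcomes"].items():
        write_sumstats(stats, out / f"outcome_{label.lower().replace(' ', '_')}.tsv")
    write_ld(bundle["ld"], out / "ld.tsv")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    manifest = dict(bundle["manifest"], seed=SEED, theta_vbi=THETA_VBI, theta_ad=0.0)
    (results / "01_instruments_manifest.json").write_text(
        json.dumps(manifest, indent=2))

    m = bundle["manifest"]
    print(f"candidate loci:        {m['n_candidates']}")
    print(f"genome-wide sig.:      {m['n_significant']}")
    print(f"clumped instruments:   {m['n_instruments']}")
    print(f"mean F statistic:      {m['mean_f']:.1f} (min {m['min_f']:.1f}, "
          f"max {m['max_f']:.1f})")
    print(f"variance explained:    {100 * m['total_r2']:.2f}%")
    print(f"bundle written to {out}")


if __name__ == "__main__":
    main()
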