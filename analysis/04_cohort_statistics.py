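#!/usr/bin/env python
"""Statistics on the 17-animal cohort.

Survival by body-armor group, organ-damage tabulation, and the Fisher exact
tests (arrest x outcome, armor x outcome).  Writes
results/cohort_stats.json.
"""

import json
from pathlib import Path

from blasttube import injury_stats as ist

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = ist.load_packaged_cohort()
    summary = ist.survival_summary(cohort)

    arrest_outcome = ist.tabulate(
        cohort, lambda r: r.respiratory_arrest, lambda r: r.died,
        row_labels=("no arrest", "arrest"), col_labels=("survived", "died"))
    fisher_ao = ist.fisher_exact_two_sided(arrest_outcome)
    armor_outcome = ist.tabulate(
        cohort, lambda r: not r.armor, lambda r: r.died,
        row_labels=("armor", "no armor"), col_labels=("survived", "died"))
    fisher_armor = ist.fisher_exact_two_sided(armor_outcome)

    out = {
        "n": summary.n,
        "n_armor": summary.n_armor,
        "mean_body_weight_kg": summary.mean_body_weight,
        "survival_percent": summary.survival_percent,
        "organ_counts": summary.organ_counts,
        "splenic_with_iah": sum(
            1 for r in cohort if {"splenic", "IAH"} <= r.organ_flags),
        "n_arrest": summary.n_arrest,
        "n_arrest_recovered": summary.n_arrest_recovered,
        "arrest_vs_outcome": {"table": arrest_outcome.array.tolist(),
                              "fisher_p": fisher_ao.p_value},
        "armor_vs_outcome": {"table": armor_outcome.array.tolist(),
                             "fisher_p": fisher_armor.p_value},
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "cohort_stats.json").write_text(json.dumps(out, indent=2) + "\n")

    print(f"n = {out['n']} ({out['n_armor']} armored), mean body weight "
          f"{out['mean_body_weight_kg']:.1f} kg")
    print(f"Survival: armor {summary.survival_percent['armor']}%, "
          f"no armor {summary.survival_percent['no_armor']}%")
    print(f"Lung hemorrhage {summary.organ_counts['LH']}/17; splenic+IAH "
          f"{out['splenic_with_iah']}/17")
    print(f"Arrests {summary.n_arrest} (recovered "
          f"{summary.n_arrest_recovered}); arrest-death Fisher p = "
          f"{fisher_ao.p_value:.3f}; armor-survival Fisher p = "
          f"{fisher_armor.p_value:.3f}")
    print(f"wrote {OUT / 'cohort_stats.json'}")


if __name__ == "__main__":
    main()
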