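#!/usr/bin/env python
"""Descriptive epidemiology of the simulated defect scores.

Reproduces the study's descriptive layer on the synthetic population from
01_simulate_population.py: per-trait summary statistics, category
prevalences, severe-category co-occurrence, the share of animals free of
all four defects, trends by birth year and inbreeding bin, and the
breeder-eligibility rule applied to severe scores.  Tables land in
results/prevalence/.
"""

import sys
from itertools import combinations
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from hoofgen.model import DEFECTS, read_phenotypes_csv
from hoofgen.prevalence import (
    breeder_eligibility,
    cooccurrence_cat2,
    descriptive_stats,
    prevalence_by_category,
    share_without_defect,
    trend_tables,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "prevalence"


def main():
    phen = read_phenotypes_csv(ROOT / "sim" / "phenotypes.csv")
    OUT.mkdir(parents=True, exist_ok=True)

    desc = descriptive_stats(phen, list(DEFECTS) + ["SDFT", "PI"])
    desc.to_csv(OUT / "descriptive_stats.csv", index=False)
    print("descriptive statistics:")
    print(desc.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    shares = pd.DataFrame(
        {t: prevalence_by_category(phen[t], [0, 1, 2]) for t in DEFECTS}
    )
    shares.index.name = "category"
    shares.to_csv(OUT / "category_shares.csv")
    print("\ncategory shares (%):")
    print(shares.round(2).to_string())
    print(f"\nshare with no defect: {share_without_defect(phen, DEFECTS):.2f}%")

    co = pd.DataFrame(
        [
            {"pair": f"{a}-{b}", "both_cat2_percent": cooccurrence_cat2(phen[a], phen[b])}
            for a, b in combinations(DEFECTS, 2)
        ]
    )
    co.to_csv(OUT / "cooccurrence_cat2.csv", index=False)
    print("\nsevere-category co-occurrence (%):")
    print(co.round(3).to_string(index=False))

    trends = trend_tables(phen, DEFECTS)
    trends["by_birth_year"].to_csv(OUT / "trend_by_birth_year.csv")
    trends["by_inbreeding"].to_csv(OUT / "trend_by_inbreeding.csv")
    print("\naffected % by inbreeding bin:")
    print(trends["by_inbreeding"].round(2).to_string())

    # severity rule: severe = category 2 of the outward defects, very severe
    # = category 2 of the inward (pigeon-toed) defects
    very_severe = (phen[["PTF", "PTR"]] == 2).sum(axis=1)
    severe = (phen[["SFF", "SFR"]] == 2).sum(axis=1)
    eligible = [
        breeder_eligibility(int(v), int(s)) for v, s in zip(very_severe, severe)
    ]
    rate = 100.0 * (1 - pd.Series(eligible).mean())
    print(f"\nbarred from breeding by the severity rule (hoof defects only): "
          f"{rate:.3f}%")


if __name__ == "__main__":
    main()
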