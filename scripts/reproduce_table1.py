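#!/usr/bin/env python
"""Recompute the descriptive table (mean, SD, relative SEM per outcome)
from a monitored cohort's data.

This is the optional data-dependent reproduction path: point it at the
deposited study data (raw epoch files or pre-computed daily summaries,
e.g. downloaded from the study's OSF repository) and it re-runs the
analysis pipeline — wear-time validation, >=21-valid-day inclusion,
variance decomposition, relative SEM — for every outcome column.

Usage:
    python scripts/reproduce_table1.py --daily-tsv daily.tsv
    python scripts/reproduce_table1.py --epoch-file epochs.csv

With --epoch-file the raw stream is processed first (60-s
re-integration, >20-min zero-run non-wear removal, >600-min valid-day
rule).  With --daily-tsv a daily-summary table (columns subject_id,
date, wear_min, ..., valid) is used directly.  Relative SEM is
evaluated at n = included subjects and m = the rounded mean number of
valid days per subject.
"""

import argparse
import sys

import pandas as pd

from actiplan import (
    anova_decompose,
    include_subjects,
    process_stream,
    read_epoch_file,
    relative_sem,
    sem,
)
from actiplan.cohort import OUTCOME_COLUMNS


def summarise(cohort, outcomes, m_reference=None):
    if m_reference is None:
        m_reference = int(round(cohort.days_per_subject().mean()))
    rows = []
    for col in outcomes:
        comp = anova_decompose(cohort, col)
        s = sem(comp.n_subjects, m_reference, comp)
        rows.append(
            {
                "outcome": col,
                "mean": cohort.data[col].mean(),
                "sd": cohort.data[col].std(ddof=1),
                "icc": comp.icc,
                "sigma_b2": comp.sigma_b2,
                "sigma_w2": comp.sigma_w2,
                "relative_sem_pct": relative_sem(s, comp.grand_mean),
            }
        )
    return pd.DataFrame(rows), m_reference


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    src = ap.add_mutually_exclusive_group(required=True)
    src.add_argument("--daily-tsv", help="daily-summary TSV (already processed)")
    src.add_argument("--epoch-file", help="raw epoch stream (subject_id, timestamp, counts)")
    ap.add_argument("--min-valid-days", type=int, default=21)
    ap.add_argument("--m-reference", type=int, default=None,
                    help="days m used in the SEM; default: rounded mean valid days")
    ap.add_argument("--outcomes", nargs="*", default=None,
                    help="outcome columns; default: all standard daily outcomes present")
    args = ap.parse_args(argv)

    if args.epoch_file:
        daily = process_stream(read_epoch_file(args.epoch_file))
    else:
        daily = pd.read_csv(args.daily_tsv, sep="\t", comment="#")
        daily["subject_id"] = daily["subject_id"].astype(str)
    cohort = include_subjects(daily, args.min_valid_days)
    if cohort.n_subjects == 0:
        print("no subjects pass the inclusion rule", file=sys.stderr)
        return 1
    outcomes = args.outcomes or [c for c in OUTCOME_COLUMNS if c in cohort.data.columns]
    table, m_ref = summarise(cohort, outcomes, args.m_reference)
    print(f"# included subjects: {cohort.n_subjects}  "
          f"(excluded: {len(cohort.exclusions)}); m = {m_ref}")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
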