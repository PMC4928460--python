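#!/usr/bin/env python
"""Group-level distribution statistics over the per-subject tables.

Averages the per-subject maxcc and ALFF distribution graphs, tests each
tissue's slope against zero, contrasts bin 10 vs bin 9 for CSF and VA, and
correlates the maxcc and ALFF group curves per tissue.

Outputs: results/group_mean_{maxcc,alff}.tsv and results/group_stats.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import slfomap as sm

ROOT = Path(__file__).resolve().parents[1]
TISSUES = ("GM", "WM", "CSF", "VA")


def load_tables(subdir, source):
    tables = []
    for sdir in sorted(p for p in subdir.iterdir() if p.is_dir()):
        df = pd.read_csv(sdir / f"distribution_{source}.tsv", sep="\t")
        tables.append(sm.DistributionTable(
            fractions=df[list(sm.TISSUE_CLASSES)].to_numpy(),
            subject_id=sdir.name, source_map=source,
        ))
    return tables


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--subjectdir", type=Path, default=ROOT / "results" / "subjects")
    ap.add_argument("--outdir", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    if not args.subjectdir.exists():
        raise SystemExit(f"{args.subjectdir} missing - run 02_subject_maps.py first")

    stats = {}
    groups = {}
    for source in ("maxcc", "alff"):
        tables = load_tables(args.subjectdir, source)
        group = sm.average_distributions(tables)
        groups[source] = group
        pd.DataFrame(group.mean_fractions, columns=list(group.classes)).to_csv(
            args.outdir / f"group_mean_{source}.tsv", sep="\t", index=False)
        slope_tests = {}
        for tissue in TISSUES:
            slopes = [sm.fit_distribution_slope(t, tissue) for t in tables]
            r = sm.test_slope_nonzero(slopes)
            slope_tests[tissue] = {
                "mean_slope": float(np.mean([s.slope for s in slopes])),
                "sd_slope": float(np.std([s.slope for s in slopes], ddof=1)),
                "t": r.t, "p": r.p,
            }
        stats[f"slope_tests_{source}"] = slope_tests
        if source == "maxcc":
            stats["bin10_vs_bin9"] = {
                tissue: dict(zip(("t", "p"), sm.compare_bins(tables, tissue, 10, 9)[:2]))
                for tissue in ("CSF", "VA")
            }

    stats["curve_correlations"] = {
        t: sm.curve_correlation(groups["maxcc"], groups["alff"], t) for t in TISSUES
    }
    (args.outdir / "group_stats.json").write_text(json.dumps(stats, indent=2))

    print("group maxcc slopes (mean ± sd across subjects):")
    for tissue in TISSUES:
        s = stats["slope_tests_maxcc"][tissue]
        print(f"  {tissue}: {s['mean_slope']:+.4f} ± {s['sd_slope']:.4f} (p={s['p']:.2e})")
    print("maxcc-vs-ALFF curve correlations:", {
        t: round(v, 3) for t, v in stats["curve_correlations"].items()})


if __name__ == "__main__":
    main()
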