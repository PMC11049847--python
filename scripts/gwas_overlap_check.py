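#!/usr/bin/env python
"""Verify anchored meta-QTL against an external GWAS MTA table.

The co-localization step compares physically anchored meta-QTL with
marker-trait associations (MTAs) from independent genome-wide association
studies: an MTA within 500 kb up/downstream of an MQTL's physical interval
counts as verification.  Published MTA coordinates are study-specific and
must be curated by the user into a ``marker chr pos_bp trait study`` table
(positions on the same assembly as the marker physical table used for
anchoring); this script then reports how many MQTL are verified and by how
many MTAs.

Usage:
    python scripts/gwas_overlap_check.py \
        --mqtl run/mqtl_physical.tsv --mta curated_mtas.tsv [--window 500000]

``--json`` prints a machine-readable summary instead of text.
"""
from __future__ import annotations

import argparse
import json
import sys

import pandas as pd

from metaqtl.anchoring import PhysicalMQTL
from metaqtl.compendium import read_mta_table
from metaqtl.integration import mta_overlap
from metaqtl.meta_clustering import MQTL


def load_physical_mqtl(path: str) -> list[PhysicalMQTL]:
    """Rebuild PhysicalMQTL objects from a pipeline ``mqtl_physical.tsv``."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        m = MQTL(mqtl_id=str(r["mqtl_id"]), chromosome=int(r["chr"]),
                 consensus_position=float(r["pos_cM"]),
                 ci95_lo=float(r["ci_lo_cM"]), ci95_hi=float(r["ci_hi_cM"]),
                 member_qtl_ids=[f"member{i}" for i in range(int(r["n_qtl"]))])
        start = None if pd.isna(r["start_bp"]) else int(r["start_bp"])
        end = None if pd.isna(r["end_bp"]) else int(r["end_bp"])
        out.append(PhysicalMQTL(mqtl=m, start_bp=start, end_bp=end,
                                anchor_quality=str(r["anchor_quality"])))
    return out


def main(argv: list[str] | None = None) -> int:
    ap = argparse.ArgumentParser(description=__doc__.split("\n")[0])
    ap.add_argument("--mqtl", required=True,
                    help="mqtl_physical.tsv from a pipeline run")
    ap.add_argument("--mta", required=True,
                    help="curated MTA table (marker chr pos_bp trait study)")
    ap.add_argument("--window", type=int, default=500_000,
                    help="bp window up/downstream (default 500 kb)")
    ap.add_argument("--json", action="store_true",
                    help="print a JSON summary")
    args = ap.parse_args(argv)

    mqtls = load_physical_mqtl(args.mqtl)
    mtas = read_mta_table(args.mta)
    report = mta_overlap(mqtls, mtas, window=args.window)

    summary = {
        "n_mqtl": len(mqtls),
        "n_mta": len(mtas),
        "n_mqtl_with_mta": report.n_mqtl_with_mta,
        "n_overlapping_mta": report.n_mta_total,
        "window_bp": args.window,
    }
    if args.json:
        print(json.dumps(summary, indent=1))
    else:
        print(f"{summary['n_mqtl_with_mta']}/{summary['n_mqtl']} MQTL overlap "
              f"{summary['n_overlapping_mta']} of {summary['n_mta']} MTAs "
              f"(±{args.window} bp)")
        for _, row in report.to_frame().sort_values(
                "n_mta", ascending=False).iterrows():
            if row["n_mta"]:
                print(f"  {row['mqtl_id']}: {row['n_mta']} MTAs")
    return 0


if __name__ == "__main__":
    sys.exit(main())
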