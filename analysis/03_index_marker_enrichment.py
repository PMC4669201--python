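"""POE enrichment among GWAS index markers (exact binomial test).

Emulates testing 88 independent genome-wide-significant index markers for
an excess of nominally significant parent-of-origin effects: a null
cohort is simulated so each index marker is directly genotyped, the POE
test is run per marker, and the one-sided exact binomial test compares
the nominal hit count against the 5% chance expectation. Also reports
the two reference tail probabilities for 3/63 and 5/88.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from poetrio.enrichment import binomial_enrichment
from poetrio.pipeline import index_marker_poe_scan
from poetrio.synthetic_data import TrioSimConfig, simulate_trio_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-index", type=int, default=88)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(args.seed)
    cohort, _ = simulate_trio_cohort(
        TrioSimConfig(seed=args.seed, n_trios=695,
                      mafs=rng.uniform(0.1, 0.5, size=args.n_index))
    )
    index = pd.DataFrame(
        {
            "snp": [m.id for m in cohort.markers],
            "chrom": [m.chrom for m in cohort.markers],
            "pos": [m.pos for m in cohort.markers],
        }
    )
    rep = index_marker_poe_scan(index, cohort, alpha=0.05)
    rep.table.to_csv(args.out / "index_scan.tsv", sep="\t", index=False,
                     float_format="%.6g")
    print(f"resolved {rep.n_resolved}/{len(index)} index markers; "
          f"{rep.n_significant} nominal POE hits at 0.05; "
          f"binomial enrichment p = {rep.binomial_p:.3f}")
    print(f"reference tails: P(X>=3 | n=63)  = {binomial_enrichment(3, 63):.3f}; "
          f"P(X>=5 | n=88) = {binomial_enrichment(5, 88):.3f}")
    print(f"wrote {args.out}/index_scan.tsv")


if __name__ == "__main__":
    main()
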