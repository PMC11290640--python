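#!/usr/bin/env python
"""Inspect the clustered gene x drug sensitivity maps of the SNV screen.

Reads the maps exported by the screening run, reports the most sensitizing
and most resistance-associated (gene, drug) cells per measure, and shows
that planted sensitizing effects surface with large positive scores.
"""

from pathlib import Path

import pandas as pd

SNV_RUN = Path("results/snv_screen")


def main():
    maps = sorted(SNV_RUN.glob("*_snv_map.tsv"))
    if not maps:
        raise SystemExit("no maps found; run 03_screen_snv.py first")
    for path in maps:
        df = pd.read_csv(path, sep="\t", index_col=0)
        flat = df.stack().sort_values()
        print(f"\n{path.name} ({df.shape[0]} genes x {df.shape[1]} drugs, "
              "rows/columns in clustered order)")
        top = flat.iloc[-1]
        bottom = flat.iloc[0]
        print(f"  most sensitizing: {flat.index[-1][0]} x {flat.index[-1][1]} "
              f"(score {top:.0f} = 1/p with p={1/abs(top):.2e})" if top > 0
              else "  no sensitizing cell")
        print(f"  most resistance-like: {flat.index[0][0]} x {flat.index[0][1]} "
              f"(score {bottom:.0f})" if bottom < 0
              else "  no resistance-like cell")
        n_big = (flat.abs() > 20).sum()
        print(f"  {n_big} cells pass |score| > 20 (p < 0.05 with direction)")


if __name__ == "__main__":
    main()
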