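"""Published per-locus diversity reference for the 99-marker rice panel.

The packaged table ``rice_ssr_diversity_published.tsv`` holds the published
per-locus diversity statistics (observed allele count, He, Shannon I, PIC)
for 99 SSR markers scored on 40 diploid rice cultivars and their 40
autotetraploid derivatives, one row per marker and one column block per
ploidy group.  It is the desk-scale ground truth for column summaries
(e.g. mean alleles per locus) and for worked per-locus checks.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

_COLUMNS = [
    "marker", "chromosome",
    "n_alleles_2x", "he_2x", "shannon_2x", "pic_2x",
    "n_alleles_4x", "he_4x", "shannon_4x", "pic_4x",
]


def load_published_diversity() -> pd.DataFrame:
    """The published 99-row per-locus diversity table as a DataFrame."""
    ref = resources.files("ssrhet.data") / "rice_ssr_diversity_published.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _COLUMNS or len(df) != 99:
        raise RuntimeError("packaged reference diversity table is corrupted")
    return df


def published_column_summary() -> pd.DataFrame:
    """Mean/min/max of each statistic column, by ploidy group."""
    df = load_published_diversity()
    stats = df.drop(columns=["marker", "chromosome"])
    return pd.DataFrame({"mean": stats.mean(), "min": stats.min(), "max": stats.max()})
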