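"""Published reference values bundled with the package.

``goose_significant_dstats.tsv`` transcribes the significant D-statistics
(|Z| > 3, p < 1e-4) reported among the True Geese (genera *Anser* and
*Branta*), one row per (P1, P2, P3) triplet against the other genus's
consensus outgroup.  It is used to validate the range of significant D
values a study of this design produces.
"""

from importlib import resources

import pandas as pd


def load_significant_dstats() -> pd.DataFrame:
    with resources.files("introphy.data").joinpath(
        "goose_significant_dstats.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def significant_d_range(decimals: int = 2) -> tuple[float, float]:
    """(min, max) of the published significant D values, rounded."""
    d = load_significant_dstats()["D"]
    return round(float(d.min()), decimals), round(float(d.max()), decimals)
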