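"""The published Sunda Arc model-comparison table, shipped as input data.

The original 191-tip weevil analysis printed, for 12 model variants under
both time-stratified and unstratified geography, the maximized
log-likelihood and free-parameter count alongside the AICc, evidence-ratio
and relative-probability columns derived from them.  Only the lnL and k
columns are inputs here; everything else is recomputed by this package's
model-selection arithmetic, and the printed derived columns are retained
solely so that the recomputation can be checked against them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: AICc sample size of the published comparison: 191 tips (190 species, one
#: of them represented by two subspecies).
PUBLISHED_N = 191


def published_comparison() -> pd.DataFrame:
    """The shipped table: columns analysis, model, free_parameters, lnL,
    aicc_printed, weight_printed, percent_printed."""
    with resources.files("decgeo.data").joinpath(
        "sunda_model_comparison.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
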