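"""Area Deprivation Index construction.

The ADI summarises 17 census-tract socioeconomic indicators (poverty,
education, housing, employment proxies) by their first principal component,
computed on the correlation matrix so heterogeneous indicator units do not
matter.  The component is oriented so that the designated poverty-proxy
indicator loads positively — deprivation increases the score — and the tract
scores are scaled to the [0, 100] range, higher meaning more deprived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, SchemaError

N_INDICATORS = 17
INDICATOR_COLUMNS = [f"v{i}" for i in range(1, N_INDICATORS + 1)]
#: ``v1`` plays the role of the poverty rate (share of population below 150%
#: of the poverty threshold) and anchors the sign of the index.
POVERTY_PROXY = "v1"


@dataclass
class AdiResult:
    """First-principal-component deprivation index over a tract table."""

    adi_by_tract: pd.Series            # tract_id -> score in [0, 100]
    loadings: pd.Series                # unit-norm eigenvector, indexed by indicator
    pc1_variance_share: float          # leading eigenvalue / 17
    dominant_variable: str             # indicator with largest |loading|
    ambiguous: bool = False            # leading eigenvalues tied within 1e-12


def _percentile_scale(scores: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    r = rankdata(scores)
    return 100.0 * (r - 1) / (len(scores) - 1)


def compute_adi(tracts: pd.DataFrame, scaling: str = "minmax") -> AdiResult:
    """Compute the ADI for every tract.

    Parameters
    ----------
    tracts : DataFrame
        Must contain ``tract_id`` and the 17 indicator columns ``v1..v17``.
    scaling : {"minmax", "percentile"}
        How raw PC1 scores are mapped to [0, 100].  ``minmax`` (default)
        uses sample min-max scaling; ``percentile`` uses percentile ranks.

    Returns an :class:`AdiResult` whose scores span exactly [0, 100] for
    non-degenerate input, with the sign convention that higher ADI means
    more deprived (positive loading on the poverty proxy).
    """
    missing = [c for c in INDICATOR_COLUMNS if c not in tracts.columns]
    if missing:
        raise SchemaError(f"tract table is missing indicator columns: {missing}")
    if "tract_id" not in tracts.columns:
        raise SchemaError("tract table is missing 'tract_id'")
    if scaling not in ("minmax", "percentile"):
        raise ValueError(f"unknown scaling '{scaling}'")
    if len(tracts) < 3:
        # two tracts are allowed only in the trivial min-max sense; guard below
        if len(tracts) < 2:
            raise DegenerateInputError("need at least 2 tracts to scale the index")

    X = tracts[INDICATOR_COLUMNS].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = INDICATOR_COLUMNS[int(np.flatnonzero(sd == 0)[0])]
        raise DegenerateInputError(f"indicator '{bad}' has zero variance across tracts")
    Z = (X - X.mean(axis=0)) / sd

    corr = (Z.T @ Z) / (len(Z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    ambiguous = bool(len(eigval) > 1 and abs(eigval[0] - eigval[1]) < 1e-12)

    v = eigvec[:, 0]
    if ambiguous:
        # deterministic tie-break: first nonzero component made positive
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            v = -v
    # orientation: deprivation (poverty proxy) increases the score
    pov = INDICATOR_COLUMNS.index(POVERTY_PROXY)
    if v[pov] < 0:
        v = -v

    scores = Z @ v
    lo, hi = scores.min(), scores.max()
    if hi - lo < 1e-12:
        raise DegenerateInputError("PC1 scores are constant; cannot scale to [0, 100]")
    if scaling == "minmax":
        adi = np.clip(100.0 * (scores - lo) / (hi - lo), 0.0, 100.0)
    else:
        adi = _percentile_scale(scores)

    loadings = pd.Series(v, index=INDICATOR_COLUMNS, name="loading")
    return AdiResult(
        adi_by_tract=pd.Series(adi, index=tracts["tract_id"].to_numpy(), name="adi"),
        loadings=loadings,
        pc1_variance_share=float(eigval[0] / N_INDICATORS),
        dominant_variable=str(loadings.abs().idxmax()),
        ambiguous=ambiguous,
    )
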