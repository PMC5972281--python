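"""Plain-text readers for moment matrices and raw-data files."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import EstimationInputError


def read_moment_matrix(path) -> np.ndarray:
    """Read a whitespace-delimited moment matrix.

    Accepts a full p x p square layout or a LISREL-style lower-triangular
    listing (p(p+1)/2 numbers, row by row, any line breaking).
    """
    values = np.array(Path(path).read_text().split(), dtype=float)
    k = values.size
    p_sq = int(round(np.sqrt(k)))
    if p_sq * p_sq == k:
        m = values.reshape(p_sq, p_sq)
        if not np.allclose(m, m.T, atol=1e-8):
            raise EstimationInputError(f"{path}: square matrix is not symmetric")
        return 0.5 * (m + m.T)
    # triangular count: k = p(p+1)/2
    p_tri = int((np.sqrt(8 * k + 1) - 1) / 2)
    if p_tri * (p_tri + 1) // 2 != k:
        raise EstimationInputError(
            f"{path}: {k} values form neither a square nor a lower triangle"
        )
    m = np.zeros((p_tri, p_tri))
    m[np.tril_indices(p_tri)] = values
    return m + np.tril(m, -1).T


def read_raw_data(path) -> pd.DataFrame:
    """Read a raw-data CSV (indicator columns, optional CASE/REP_ROW labels)."""
    return pd.read_csv(path)
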