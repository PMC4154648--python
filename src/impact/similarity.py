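"""Profile-similarity primitives shared by the set- and network-based search.

Similarity between two phenotypic profiles is the Pearson correlation
coefficient; a :class:`SimilarityPolicy` turns a correlation into a binary
"similar" call, either one-sided (``r >= T``, used by the set search) or on
the absolute value (``|r| >= T``, used by seed selection and module
expansion).  Thresholds are closed (``>=``).  Undefined correlations
(zero-variance or missing-data profiles) are never similar.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .screen import Profile

__all__ = ["SimilarityPolicy", "pearson", "similarity_matrix", "SimilarityMatrix", "is_similar"]


@dataclass(frozen=True)
class SimilarityPolicy:
    """Threshold ``T`` plus the mode deciding how the sign of ``r`` is used."""

    T: float
    mode: str = "positive"  # "positive" (r >= T) or "absolute" (|r| >= T)

    def __post_init__(self) -> None:
        if not 0 < self.T <= 1:
            raise ValueError("similarity threshold T must be in (0, 1]")
        if self.mode not in ("positive", "absolute"):
            raise ValueError(f"unknown similarity mode {self.mode!r}")


@dataclass
class SimilarityMatrix:
    """Pairwise Pearson correlations over a list of profiles."""

    values: np.ndarray
    profile_index: list[tuple[str, str]]  # (gene, oligo_id) per row


def _as_values(p) -> np.ndarray:
    if isinstance(p, Profile):
        return p.values
    return np.asarray(p, dtype=float)


def pearson(a, b) -> float:
    """Pearson ``r`` of two profiles; NaN when undefined.

    Undefined means: unequal/short length, non-finite entries, or zero
    variance in either argument.  Callers treat NaN as "not similar".
    """
    x = _as_values(a)
    y = _as_values(b)
    if x.shape != y.shape or x.size < 2:
        return float("nan")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        return float("nan")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt((xd * xd).sum())
    sy = np.sqrt((yd * yd).sum())
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.clip((xd * yd).sum() / (sx * sy), -1.0, 1.0))


def similarity_matrix(profiles: Sequence[Profile]) -> SimilarityMatrix:
    """All pairwise correlations; NaN marks undefined pairs."""
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    x = np.asarray([_as_values(p) for p in profiles], dtype=float)
    n = x.shape[1]
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    bad = ~np.isfinite(x).all(axis=1) | (sd[:, 0] == 0)
    z[bad] = np.nan
    r = z @ z.T / n
    np.clip(r, -1.0, 1.0, out=r)
    valid = ~bad
    r[valid, valid] = 1.0
    index = [
        (p.gene, p.oligo_id) if isinstance(p, Profile) else (str(i), str(i))
        for i, p in enumerate(profiles)
    ]
    return SimilarityMatrix(r, index)


def is_similar(r: float, policy: SimilarityPolicy) -> bool:
    """Binary similarity call; undefined (NaN) is never similar."""
    if r is None or np.isnan(r):
        return False
    if policy.mode == "positive":
        return bool(r >= policy.T)
    return bool(abs(r) >= policy.T)
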