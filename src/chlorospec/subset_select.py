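"""Kennard-Stone calibration sample selection.

Kennard-Stone (KS) is a deterministic max-min design: the first two
selections are the globally most distant pair (Euclidean), and every
subsequent selection maximises its minimum distance to the points already
selected. Running KS once to the largest requested size yields nested
subsets for free — the first ``m`` selections of a longer run are exactly
the KS selection of size ``m`` (prefix property), which is how the serial
subset sweep (60, 100, ..., 260 out of a 280-sample calibration pool) is
produced.

Ties are broken towards the lowest index, which makes the algorithm fully
deterministic (no seed is involved).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_SUBSET_SIZES = (60, 100, 140, 180, 220, 260)


@dataclass(frozen=True)
class SubsetPlan:
    """Serial subset sizes and the space KS runs in.

    sizes
        Strictly increasing subset sizes (default 60..260 step 40).
    space
        ``"pc-scores"`` (KS on principal-component scores retaining
        ``pc_variance`` of spectral variance — the chemometrics default)
        or ``"raw-spectra"``.
    pc_variance
        Variance fraction retained when ``space == "pc-scores"``.
    """

    sizes: tuple[int, ...] = DEFAULT_SUBSET_SIZES
    space: str = "pc-scores"
    pc_variance: float = 0.99

    def __post_init__(self) -> None:
        sizes = tuple(int(x) for x in self.sizes)
        object.__setattr__(self, "sizes", sizes)
        if len(sizes) == 0 or any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError(f"sizes must be strictly increasing, got {sizes}")
        if sizes[0] < 2:
            raise ValueError("smallest subset size must be >= 2")
        if self.space not in ("pc-scores", "raw-spectra"):
            raise ValueError(f"unknown space {self.space!r}")


def kennard_stone(points: np.ndarray, m: int) -> np.ndarray:
    """Select ``m`` well-spread rows of ``points``; returns indices in
    selection order.

    The first two indices are the most distant pair; each later index
    maximises the minimum Euclidean distance to the selected set. Ties go
    to the lowest index (for the initial pair, the lexicographically
    smallest pair).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if m < 2:
        raise ValueError(f"Kennard-Stone needs m >= 2, got {m}")
    if m > n:
        raise ValueError(f"cannot select {m} from {n} points")
    if np.isnan(points).any():
        raise ValueError("points contain NaN")

    sq = np.einsum("ij,ij->i", points, points)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (points @ points.T)
    np.maximum(d2, 0.0, out=d2)
    # lexicographically smallest among maximal pairs: flat argmax scans
    # row-major, i.e. (0,1) before (0,2) before (1,2)
    iu = np.triu_indices(n, k=1)
    flat = np.argmax(d2[iu])
    first, second = int(iu[0][flat]), int(iu[1][flat])

    selected = np.empty(m, dtype=int)
    selected[0], selected[1] = first, second
    min_d2 = np.minimum(d2[first], d2[second])
    min_d2[first] = min_d2[second] = -np.inf
    for t in range(2, m):
        nxt = int(np.argmax(min_d2))  # argmax -> first (lowest) index on ties
        selected[t] = nxt
        np.minimum(min_d2, d2[nxt], out=min_d2)
        min_d2[nxt] = -np.inf
    return selected


def nested_subsets(points: np.ndarray, plan: SubsetPlan) -> dict[int, np.ndarray]:
    """One KS run of length max(sizes); subset ``s`` is its first ``s``
    selections, so subsets are nested by construction."""
    n = np.atleast_2d(points).shape[0]
    biggest = plan.sizes[-1]
    if biggest > n:
        raise ValueError(f"largest subset size {biggest} exceeds pool size {n}")
    order = kennard_stone(points, biggest)
    return {size: order[:size].copy() for size in plan.sizes}


def ks_split(points: np.ndarray, n_cal: int) -> tuple[np.ndarray, np.ndarray]:
    """Split a pool into a KS-selected calibration set and the remainder.

    Returns ``(calibration_indices, validation_indices)``; calibration in
    KS selection order, validation in original order. The study design
    selects 280 calibration samples from the 350-sample pool, leaving 70
    for validation.
    """
    points = np.atleast_2d(points)
    cal = kennard_stone(points, n_cal)
    mask = np.ones(points.shape[0], dtype=bool)
    mask[cal] = False
    return cal, np.flatnonzero(mask)
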