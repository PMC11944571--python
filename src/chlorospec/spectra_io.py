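"""Spectral table I/O and the core :class:`SpectraSet` container.

Leaf reflectance spectra are exchanged as CSV in two dialects:

* **wide** — first column ``sample_id``, remaining headers numeric
  wavelengths in nm, one row per sample (the canonical format, matching
  common portable-spectrometer exports);
* **long** — three columns ``sample_id,wavelength,value``.

Sample metadata travels in a separate CSV with the fixed header
``sample_id,chlorophyll,species,month,replicate``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

WAVELENGTH_MIN_NM = 350.0
WAVELENGTH_MAX_NM = 2500.0

METADATA_COLUMNS = ["sample_id", "chlorophyll", "species", "month", "replicate"]
MONTH_MIN, MONTH_MAX = 2, 11  # study window: February-November


class SpectraError(ValueError):
    """Raised when a spectral table violates a structural invariant."""


@dataclass
class SpectraSet:
    """Wavelength grid plus a samples-by-wavelengths value matrix.

    Parameters
    ----------
    wavelengths
        Strictly increasing nm values within [350, 2500].
    values
        ``(n_samples, n_wavelengths)`` real matrix. Reflectance values must
        lie in (0, 1]; absorbance values must be non-negative. NaNs are a
        hard error (no imputation — downstream KDE/PLSR assume complete
        matrices).
    mode
        ``"reflectance"`` or ``"absorbance"``.
    sample_ids
        Unique sample identifiers, one per row.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    mode: str
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        self._validate()

    def _validate(self) -> None:
        if self.mode not in ("reflectance", "absorbance"):
            raise SpectraError(f"unknown mode {self.mode!r}")
        wl = self.wavelengths
        if wl.ndim != 1 or wl.size == 0:
            raise SpectraError("wavelengths must be a non-empty 1-D vector")
        if np.any(np.diff(wl) <= 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if wl[0] < WAVELENGTH_MIN_NM or wl[-1] > WAVELENGTH_MAX_NM:
            raise SpectraError(
                f"wavelengths must lie within [{WAVELENGTH_MIN_NM:g}, "
                f"{WAVELENGTH_MAX_NM:g}] nm, got [{wl[0]:g}, {wl[-1]:g}]"
            )
        if self.values.shape != (len(self.sample_ids), wl.size):
            raise SpectraError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {wl.size} wavelengths"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            seen: set[str] = set()
            dups = sorted({s for s in self.sample_ids if s in seen or seen.add(s)})
            raise SpectraError(f"duplicate sample ids: {dups}")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise SpectraError(
                f"NaN value at sample {self.sample_ids[i]!r}, "
                f"wavelength {wl[j]:g} nm (missing cells are not imputed)"
            )
        if self.mode == "reflectance":
            bad = (self.values <= 0) | (self.values > 1)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise SpectraError(
                    f"reflectance outside (0, 1] at sample "
                    f"{self.sample_ids[i]!r}, wavelength {wl[j]:g} nm "
                    f"(value {self.values[i, j]:g})"
                )
        elif (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise SpectraError(
                f"negative absorbance at sample {self.sample_ids[i]!r}, "
                f"wavelength {wl[j]:g} nm"
            )

    # -- convenience -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def copy(self) -> "SpectraSet":
        return replace(
            self,
            wavelengths=self.wavelengths.copy(),
            values=self.values.copy(),
            sample_ids=list(self.sample_ids),
        )

    def take(self, indices: Sequence[int]) -> "SpectraSet":
        """Row subset preserving the given order."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            wavelengths=self.wavelengths.copy(),
            values=self.values[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def band(self, lo: float, hi: float) -> "SpectraSet":
        """Column subset on the half-open nm interval ``[lo, hi)``."""
        mask = (self.wavelengths >= lo) & (self.wavelengths < hi)
        if not mask.any():
            raise SpectraError(f"no wavelengths in [{lo:g}, {hi:g}) nm")
        return replace(
            self,
            wavelengths=self.wavelengths[mask].copy(),
            values=self.values[:, mask].copy(),
            sample_ids=list(self.sample_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.wavelengths)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def read_spectra(
    path: str | Path, layout: str = "wide", mode: str | None = None
) -> SpectraSet:
    """Read a spectral CSV in the wide or long dialect.

    Wavelengths are sorted ascending; sample ids keep file order. The
    returned set is validated (see :class:`SpectraSet`). When ``mode`` is
    None it is inferred: reflectance if all values lie in (0, 1],
    absorbance otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "wide":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.columns[0] != "sample_id":
            raise SpectraError(
                f"wide spectra CSV must start with a 'sample_id' column, "
                f"got {df.columns[0]!r}"
            )
        try:
            wl = np.array([float(c) for c in df.columns[1:]])
        except ValueError as exc:
            raise SpectraError(f"non-numeric wavelength header: {exc}") from exc
        ids = df["sample_id"].astype(str).tolist()
        values = df.iloc[:, 1:].to_numpy(dtype=float)
    elif layout == "long":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"sample_id", "wavelength", "value"}
        if not required.issubset(df.columns):
            raise SpectraError(
                f"long spectra CSV needs columns {sorted(required)}"
            )
        ids = list(dict.fromkeys(df["sample_id"].astype(str)))
        wide = df.pivot(index="sample_id", columns="wavelength", values="value")
        wide = wide.loc[ids]
        wl = wide.columns.to_numpy(dtype=float)
        values = wide.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    order = np.argsort(wl, kind="stable")
    wl_sorted = wl[order]
    if np.any(np.diff(wl_sorted) <= 0):
        raise SpectraError("wavelength grid contains duplicates")
    if mode is None:
        in_unit = np.nanmax(values) <= 1 and np.nanmin(values) > 0
        mode = "reflectance" if in_unit else "absorbance"
    return SpectraSet(wl_sorted, values[:, order], mode, ids)


def write_spectra(s: SpectraSet, path: str | Path, layout: str = "wide") -> Path:
    """Write a spectral CSV; round-trips values to full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if layout == "wide":
        df = pd.DataFrame(s.values, columns=[repr(float(w)) for w in s.wavelengths])
        df.insert(0, "sample_id", s.sample_ids)
        df.to_csv(path, index=False, float_format="%.17g")
    elif layout == "long":
        rows = pd.DataFrame(
            {
                "sample_id": np.repeat(s.sample_ids, s.n_wavelengths),
                "wavelength": np.tile(s.wavelengths, s.n_samples),
                "value": s.values.ravel(),
            }
        )
        rows.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return path


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample-metadata CSV."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    return validate_metadata(df)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta.to_csv(path, index=False, float_format="%.17g")
    return path


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise SpectraError(f"metadata missing columns {missing}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dups = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"])
        raise SpectraError(f"duplicate sample ids in metadata: {dups}")
    chl = meta["chlorophyll"].to_numpy(dtype=float)
    present = ~np.isnan(chl)
    if np.any(~np.isfinite(chl[present])) or np.any(chl[present] < 0):
        raise SpectraError("chlorophyll must be finite and >= 0 when present")
    months = meta["month"].to_numpy(dtype=int)
    if months.min() < MONTH_MIN or months.max() > MONTH_MAX:
        raise SpectraError(
            f"month outside study window {MONTH_MIN}-{MONTH_MAX} "
            f"(February-November)"
        )
    return meta


def join_metadata(
    spectra: SpectraSet, meta: pd.DataFrame, strict: bool = True
) -> tuple[SpectraSet, pd.DataFrame, int]:
    """Inner-join spectra with metadata on ``sample_id``.

    Output sample order equals the spectra input order. In strict mode every
    spectra id must be present in the metadata; in lenient mode unmatched
    spectra are dropped with a warning.

    Returns
    -------
    (joined spectra, aligned metadata, number of dropped spectra rows)
    """
    meta = validate_metadata(meta)
    meta_ids = set(meta["sample_id"])
    keep = [i for i, sid in enumerate(spectra.sample_ids) if sid in meta_ids]
    dropped = spectra.n_samples - len(keep)
    if not keep:
        raise SpectraError("no overlap between spectra and metadata sample ids")
    if dropped and strict:
        missing = [s for s in spectra.sample_ids if s not in meta_ids]
        raise SpectraError(
            f"{dropped} spectra sample(s) missing from metadata "
            f"(strict mode): {missing[:10]}"
        )
    if dropped:
        warnings.warn(
            f"dropped {dropped} spectra sample(s) without metadata",
            stacklevel=2,
        )
    joined = spectra.take(keep)
    aligned = (
        meta.set_index("sample_id").loc[joined.sample_ids].reset_index()
    )
    return joined, aligned, dropped
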