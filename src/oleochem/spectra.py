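"""Spectral containers and I/O.

A :class:`Spectrum` is an absorbance trace on a wavenumber grid plus sample
metadata; a :class:`SpectrumSet` is an ordered collection of spectra sharing
one grid.  Grids are stored high-to-low (4000 -> 650 cm^-1, the usual
spectrometer presentation); ascending input is flipped on construction so
every module downstream can rely on the descending convention.

Spectra move between memory and disk as wide CSV tables (wavenumber in the
first column, one column per sample) with a ``<stem>_meta.csv`` sidecar that
carries per-sample metadata.  A minimal JCAMP-DX reader for fixed-step
``XYDATA=(X++(Y..Y))`` records is also provided.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OIL_TYPES",
    "SampleMeta",
    "Spectrum",
    "SpectrumSet",
    "RegionSpec",
    "crop_region",
    "crop_set",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_jcamp",
]

#: Recognised oil-type codes: camellia, rapeseed, soybean, corn, sunflower,
#: peanut and sesame oil, plus BLEND for binary admixtures.
OIL_TYPES = ("CAO", "RSO", "SBO", "CO", "SFO", "PO", "SO", "BLEND")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata.

    ``blend_fraction_v`` is the adulterant volume fraction in % v/v: 0 for a
    pure base oil, 100 for the pure adulterant, strictly between 0 and 100
    if and only if the sample is a BLEND.
    """

    sample_id: str
    oil_type: str
    blend_fraction_v: float = 0.0
    base_brand: str = ""
    adulterant_brand: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.oil_type not in OIL_TYPES:
            raise ValueError(
                f"unknown oil_type {self.oil_type!r} for sample {self.sample_id!r};"
                f" expected one of {OIL_TYPES}"
            )
        v = float(self.blend_fraction_v)
        if not 0.0 <= v <= 100.0:
            raise ValueError(
                f"blend_fraction_v={v} out of [0, 100] for sample {self.sample_id!r}"
            )
        is_blend = 0.0 < v < 100.0
        if is_blend != (self.oil_type == "BLEND"):
            raise ValueError(
                f"sample {self.sample_id!r}: oil_type must be BLEND iff "
                f"0 < blend_fraction_v < 100 (got {self.oil_type}, {v})"
            )
        if int(self.replicate) < 1:
            raise ValueError(f"replicate must be a positive integer, got {self.replicate}")


@dataclass
class Spectrum:
    """One absorbance spectrum: strictly descending wavenumber grid (cm^-1),
    finite absorbance values (AU) and sample metadata."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: SampleMeta

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=np.float64)
        ab = np.asarray(self.absorbance, dtype=np.float64)
        if wn.ndim != 1 or ab.ndim != 1 or wn.size != ab.size or wn.size < 2:
            raise ValueError("wavenumbers and absorbance must be equal-length 1-D arrays of size >= 2")
        d = np.diff(wn)
        if np.all(d > 0):  # ascending input: normalise to descending storage
            wn, ab = wn[::-1].copy(), ab[::-1].copy()
        elif not np.all(d < 0):
            raise ValueError(f"wavenumber grid of {self.meta.sample_id!r} is not strictly monotonic")
        if not np.all(np.isfinite(ab)):
            raise ValueError(f"non-finite absorbance in sample {self.meta.sample_id!r}")
        self.wavenumbers = wn
        self.absorbance = ab

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_absorbance(self, ab: np.ndarray) -> "Spectrum":
        """Copy with new absorbance values on the same grid and metadata."""
        return Spectrum(self.wavenumbers.copy(), np.asarray(ab, dtype=np.float64), self.meta)


class SpectrumSet:
    """Ordered collection of spectra sharing one (bitwise identical) grid."""

    def __init__(self, spectra: Iterable[Spectrum]):
        self.spectra: list[Spectrum] = list(spectra)
        if self.spectra:
            grid = self.spectra[0].wavenumbers
            for s in self.spectra[1:]:
                if s.wavenumbers.shape != grid.shape or not np.array_equal(s.wavenumbers, grid):
                    raise ValueError(
                        f"sample {s.meta.sample_id!r} is not on the shared wavenumber grid"
                    )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i) -> Spectrum:
        return self.spectra[i]

    @property
    def grid(self) -> np.ndarray:
        if not self.spectra:
            raise ValueError("empty SpectrumSet has no grid")
        return self.spectra[0].wavenumbers

    @property
    def sample_ids(self) -> list[str]:
        return [s.meta.sample_id for s in self.spectra]

    @property
    def metas(self) -> list[SampleMeta]:
        return [s.meta for s in self.spectra]

    def to_matrix(self) -> np.ndarray:
        """Stack absorbances into an (n_samples, n_points) matrix."""
        if not self.spectra:
            raise ValueError("empty SpectrumSet")
        return np.vstack([s.absorbance for s in self.spectra])

    def subset(self, predicate) -> "SpectrumSet":
        return SpectrumSet([s for s in self.spectra if predicate(s.meta)])

    def map(self, fn) -> "SpectrumSet":
        return SpectrumSet([fn(s) for s in self.spectra])


@dataclass(frozen=True)
class RegionSpec:
    """Spectral windows as (high, low) cm^-1 pairs, closed at both ends."""

    windows: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        wins = tuple((float(h), float(l)) for h, l in self.windows)
        for h, l in wins:
            if not h > l:
                raise ValueError(f"window ({h}, {l}) must satisfy high > low")
        ordered = sorted(wins, key=lambda w: -w[0])
        for (h1, l1), (h2, l2) in zip(ordered, ordered[1:]):
            if h2 >= l1:
                raise ValueError(f"windows ({h1},{l1}) and ({h2},{l2}) overlap")
        object.__setattr__(self, "windows", wins)

    @property
    def label(self) -> str:
        return ",".join(f"{h:g}-{l:g}" for h, l in self.windows)

    @classmethod
    def parse(cls, text: str) -> "RegionSpec":
        """Parse e.g. ``"1800-650,3050-2750"`` into a RegionSpec."""
        wins = []
        for part in text.split(","):
            h, l = part.strip().split("-")
            wins.append((float(h), float(l)))
        return cls(tuple(wins))


def crop_region(s: Spectrum, region: RegionSpec) -> Spectrum:
    """Keep grid points falling inside any window (endpoints inclusive).

    Order and metadata are preserved.  A window with no grid point inside it
    is an error (it would silently drop a requested range).
    """
    wn = s.wavenumbers
    mask = np.zeros(wn.size, dtype=bool)
    for h, l in region.windows:
        inside = (wn >= l) & (wn <= h)
        if not inside.any():
            raise ValueError(f"window ({h}, {l}) lies entirely outside the grid "
                             f"[{wn.min():g}, {wn.max():g}]")
        mask |= inside
    return Spectrum(wn[mask].copy(), s.absorbance[mask].copy(), s.meta)


def crop_set(sset: SpectrumSet, region: RegionSpec) -> SpectrumSet:
    return sset.map(lambda s: crop_region(s, region))


# ---------------------------------------------------------------------------
# CSV I/O

_META_COLUMNS = ["sample_id", "oil_type", "blend_fraction_v",
                 "base_brand", "adulterant_brand", "replicate"]


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + "_meta" + path.suffix)


def write_spectra_csv(sset: SpectrumSet, path) -> Path:
    """Write a wide CSV (wavenumber first column, one column per sample) plus
    a ``<stem>_meta.csv`` sidecar; returns the spectra path."""
    if len(sset) == 0:
        raise ValueError("cannot write an empty SpectrumSet")
    ids = sset.sample_ids
    if len(set(ids)) != len(ids):
        raise ValueError("sample_ids must be unique to serialise as CSV columns")
    path = Path(path)
    data = {"wavenumber_cm1": sset.grid}
    for s in sset:
        data[s.meta.sample_id] = s.absorbance
    # repr of a Python float is the shortest decimal that round-trips exactly
    pd.DataFrame(data).to_csv(path, index=False,
                              float_format=lambda x: repr(float(x)))
    meta = pd.DataFrame(
        [{c: getattr(s.meta, c) for c in _META_COLUMNS} for s in sset]
    )
    meta.to_csv(_meta_path(path), index=False)
    return path


def read_spectra_csv(path) -> SpectrumSet:
    """Read a wide spectra CSV and its metadata sidecar back into a SpectrumSet."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a wavenumber column plus >= 1 sample column")
    meta_file = _meta_path(path)
    if not meta_file.exists():
        raise FileNotFoundError(f"metadata sidecar {meta_file} not found")
    meta_df = pd.read_csv(meta_file).fillna({"base_brand": "", "adulterant_brand": ""})
    meta_df["base_brand"] = meta_df["base_brand"].fillna("").astype(str)
    meta_df["adulterant_brand"] = meta_df["adulterant_brand"].fillna("").astype(str)
    by_id = {row.sample_id: row for row in meta_df.itertuples(index=False)}
    grid = df.iloc[:, 0].to_numpy(dtype=np.float64)
    spectra = []
    for col in df.columns[1:]:
        if col not in by_id:
            raise KeyError(f"no metadata row for sample {col!r} in {meta_file}")
        r = by_id[col]
        meta = SampleMeta(
            sample_id=str(r.sample_id),
            oil_type=str(r.oil_type),
            blend_fraction_v=float(r.blend_fraction_v),
            base_brand=str(r.base_brand) if r.base_brand == r.base_brand else "",
            adulterant_brand=str(r.adulterant_brand) if r.adulterant_brand == r.adulterant_brand else "",
            replicate=int(r.replicate),
        )
        spectra.append(Spectrum(grid.copy(), df[col].to_numpy(dtype=np.float64), meta))
    return SpectrumSet(spectra)


# ---------------------------------------------------------------------------
# Minimal JCAMP-DX reader

def read_jcamp(path, sample_id: str | None = None, oil_type: str = "CAO") -> Spectrum:
    """Read a fixed-step JCAMP-DX file with ``XYDATA=(X++(Y..Y))`` records.

    Only the subset needed for spectrometer exports is supported: FIRSTX,
    LASTX, NPOINTS, XFACTOR, YFACTOR headers and plain space-separated
    numeric data lines (no DIFDUP compression).
    """
    path = Path(path)
    headers: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            if key == "XYDATA":
                if "X++(Y..Y)" not in value.replace(" ", ""):
                    raise ValueError(f"unsupported XYDATA form {value!r}")
                in_data = True
            elif key == "END":
                in_data = False
            else:
                headers[key] = value.strip()
            continue
        if in_data:
            nums = [float(tok) for tok in re.split(r"[,\s]+", line) if tok]
            ys.extend(nums[1:])  # first number on each line is the X of that line
    for req in ("FIRSTX", "LASTX", "NPOINTS"):
        if req not in headers:
            raise ValueError(f"{path}: missing ##{req}= header")
    n = int(float(headers["NPOINTS"]))
    firstx, lastx = float(headers["FIRSTX"]), float(headers["LASTX"])
    xfactor = float(headers.get("XFACTOR", 1.0))
    yfactor = float(headers.get("YFACTOR", 1.0))
    if len(ys) != n:
        raise ValueError(f"{path}: expected {n} Y values, found {len(ys)}")
    wn = np.linspace(firstx * xfactor, lastx * xfactor, n)
    ab = np.asarray(ys, dtype=np.float64) * yfactor
    sid = sample_id or headers.get("TITLE", path.stem)
    return Spectrum(wn, ab, SampleMeta(sample_id=sid, oil_type=oil_type))
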