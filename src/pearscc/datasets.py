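"""Core data containers for Vis/NIR calibration work.

A :class:`SpectraSet` holds a wavelength grid and one reflectance row per
sample (or per replicate scan); a :class:`ReferenceSet` holds the gravimetric
stone cell content (SCC, % by mass) measured for the same samples.  Alignment
between the two is always by exact sample-id match, never by row order, so
that mismatched files fail loudly.

The module also carries the small amount of reference-side arithmetic the
pipeline needs: the gravimetric SCC formula, wavelength-range trimming,
replicate averaging, descriptive statistics and a two-group one-way ANOVA.
"""
from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats


class ParseError(ValueError):
    """A delimited-text file could not be parsed into a valid data set."""


@dataclass(frozen=True)
class SpectraSet:
    """Wavelength grid plus a samples x channels reflectance matrix.

    Parameters
    ----------
    wavelengths
        Channel centers in nm, strictly increasing.
    reflectance
        Matrix with one row per sample and one column per channel.  Values
        are unitless (raw counts, relative reflectance or preprocessed
        spectra all flow through the same container).
    sample_ids
        Unique row labels.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        refl = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        ids = tuple(str(s) for s in self.sample_ids)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", refl)
        object.__setattr__(self, "sample_ids", ids)
        if wl.ndim != 1:
            raise ValueError("wavelengths must be a 1-D vector")
        if refl.shape[1] != wl.size:
            raise ValueError(
                f"reflectance has {refl.shape[1]} columns but "
                f"{wl.size} wavelengths were given"
            )
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if len(ids) != refl.shape[0]:
            raise ValueError(
                f"{len(ids)} sample ids for {refl.shape[0]} spectra rows"
            )
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if not np.all(np.isfinite(refl)):
            raise ValueError("reflectance contains non-finite values")
        if not np.all(np.isfinite(wl)):
            raise ValueError("wavelengths contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.reflectance.shape[1]

    def select_channels(self, idx: Sequence[int]) -> "SpectraSet":
        """Return a copy restricted to the given channel indices (kept in
        ascending wavelength order)."""
        idx = np.asarray(idx, dtype=int)
        order = np.sort(idx)
        return SpectraSet(self.wavelengths[order], self.reflectance[:, order],
                          self.sample_ids)

    def with_reflectance(self, matrix: np.ndarray) -> "SpectraSet":
        return SpectraSet(self.wavelengths, matrix, self.sample_ids)


@dataclass(frozen=True)
class ReferenceSet:
    """Per-sample SCC values (% mass fraction), aligned to spectra by id."""

    sample_ids: tuple[str, ...]
    scc: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.sample_ids)
        scc = np.asarray(self.scc, dtype=float).ravel()
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "scc", scc)
        if len(ids) != scc.size:
            raise ValueError("one SCC value per sample id required")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in reference set")
        if not np.all(np.isfinite(scc)) or np.any(scc <= 0):
            raise ValueError("SCC values must be finite and strictly positive")
        if np.any(scc >= 100):
            raise ValueError("SCC is a percent mass fraction in (0, 100)")

    def aligned_to(self, spectra: SpectraSet) -> np.ndarray:
        """SCC values reordered to match ``spectra.sample_ids``.

        Raises ``KeyError`` for any spectra id without a reference value.
        """
        lookup = {s: v for s, v in zip(self.sample_ids, self.scc)}
        missing = [s for s in spectra.sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"no reference SCC for sample ids {missing[:5]}")
        return np.array([lookup[s] for s in spectra.sample_ids])


@dataclass(frozen=True)
class SccMeasurement:
    """Masses from the gravimetric stone-cell assay (all in grams)."""

    m_total: float   # filter paper + dried stone cells
    m_filter: float  # filter paper alone
    m_pulp: float    # pulp cut around the scanned points

    def __post_init__(self) -> None:
        for name in ("m_total", "m_filter", "m_pulp"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.m_total < self.m_filter:
            raise ValueError("m_total < m_filter implies negative stone mass")


@dataclass(frozen=True)
class SetStatistics:
    """Descriptive statistics of a vector of SCC values (all in %)."""

    n: int
    min: float
    max: float
    mean: float
    sd: float
    sd_degenerate: bool = False

    def to_dict(self) -> dict:
        return {"n": self.n, "min": self.min, "max": self.max,
                "mean": self.mean, "sd": self.sd,
                "sd_degenerate": self.sd_degenerate}


# ---------------------------------------------------------------------------
# delimited-text I/O
#
# Canonical spectra CSV: header "id,<wl1>,<wl2>,...", one row per sample.
# Reference CSV: header "id,scc_percent".  UTF-8, "." decimal, "," delimiter.
# Floats are written with repr() so a write -> read round trip is exact.
# ---------------------------------------------------------------------------

def read_spectra(path: str | Path, require_nonnegative: bool = False) -> SpectraSet:
    """Read a spectra CSV in the canonical layout.

    Raises :class:`ParseError` naming the offending row/column on malformed
    headers, ragged rows, non-numeric cells or duplicate ids.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if len(header) < 2 or header[0] != "id":
            raise ParseError(f"{path}: header must start with 'id' followed "
                             "by wavelength values")
        try:
            wavelengths = [float(w) for w in header[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric wavelength in header: {exc}")
        ids: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: row {lineno} has {len(row)} fields, "
                    f"expected {len(header)}")
            sid = row[0]
            if sid in seen:
                raise ParseError(f"{path}: duplicate sample id {sid!r} "
                                 f"at row {lineno}")
            seen.add(sid)
            try:
                values = [float(x) for x in row[1:]]
            except ValueError:
                bad = next(j for j, x in enumerate(row[1:], start=2)
                           if not _is_number(x))
                raise ParseError(f"{path}: non-numeric cell at row {lineno}, "
                                 f"column {bad}") from None
            ids.append(sid)
            rows.append(values)
    if not rows:
        raise ParseError(f"{path}: no sample rows")
    matrix = np.array(rows, dtype=float)
    if require_nonnegative and np.any(matrix < 0):
        raise ParseError(f"{path}: negative reflectance values present")
    return SpectraSet(np.array(wavelengths), matrix, tuple(ids))


def _is_number(x: str) -> bool:
    try:
        float(x)
        return True
    except ValueError:
        return False


def write_spectra(s: SpectraSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id"] + [repr(float(w)) for w in s.wavelengths])
        for sid, row in zip(s.sample_ids, s.reflectance):
            writer.writerow([sid] + [repr(float(v)) for v in row])


def read_reference(path: str | Path) -> ReferenceSet:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or header[:2] != ["id", "scc_percent"]:
            raise ParseError(f"{path}: expected header 'id,scc_percent'")
        ids, values = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 2:
                raise ParseError(f"{path}: row {lineno} is missing fields")
            ids.append(row[0])
            try:
                values.append(float(row[1]))
            except ValueError:
                raise ParseError(f"{path}: non-numeric SCC at row "
                                 f"{lineno}") from None
    try:
        return ReferenceSet(tuple(ids), np.array(values))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_reference(r: ReferenceSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "scc_percent"])
        for sid, v in zip(r.sample_ids, r.scc):
            writer.writerow([sid, repr(float(v))])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def trim_to_effective_range(s: SpectraSet, low_nm: float,
                            high_nm: float) -> SpectraSet:
    """Keep exactly the channels with ``low_nm <= wavelength <= high_nm``.

    The interval is closed; channel order is preserved.  Spectrometer output
    is noisy at both ends of its range, so modeling is restricted to an
    effective window (498-1020 nm for the pear instrument).
    """
    if not low_nm < high_nm:
        raise ValueError("low_nm must be below high_nm")
    mask = (s.wavelengths >= low_nm) & (s.wavelengths <= high_nm)
    if not mask.any():
        raise ValueError(
            f"no channel lies in [{low_nm}, {high_nm}] nm")
    return SpectraSet(s.wavelengths[mask], s.reflectance[:, mask],
                      s.sample_ids)


def average_replicates(s: SpectraSet,
                       group_map: Mapping[str, str]) -> SpectraSet:
    """Average replicate scans (e.g. three 120-degree rotations) per sample.

    ``group_map`` maps every replicate id to its sample id.  Output has one
    row per group, each channel the arithmetic mean over the group's
    replicates; groups appear in order of first appearance.
    """
    missing = [sid for sid in s.sample_ids if sid not in group_map]
    if missing:
        raise ValueError(f"replicate ids without a group: {missing[:5]}")
    order: list[str] = []
    members: dict[str, list[int]] = {}
    for i, sid in enumerate(s.sample_ids):
        g = group_map[sid]
        if g not in members:
            members[g] = []
            order.append(g)
        members[g].append(i)
    empty = [g for g, rows in members.items() if not rows]
    if empty:
        raise ValueError(f"group(s) with zero members: {empty}")
    rows = np.stack([s.reflectance[members[g]].mean(axis=0) for g in order])
    return SpectraSet(s.wavelengths, rows, tuple(order))


def replicate_groups(ids: Iterable[str], sep: str = "_r") -> dict[str, str]:
    """Group map derived from replicate ids of the form ``<sample><sep><k>``.

    Ids without the separator map to themselves (single scans).
    """
    out = {}
    for sid in ids:
        base, _, tail = sid.rpartition(sep)
        out[sid] = base if base and tail.isdigit() else sid
    return out


def compute_scc(m: SccMeasurement) -> float:
    """Gravimetric stone cell content in percent of pulp mass:
    ``(m_total - m_filter) / m_pulp * 100``."""
    return (m.m_total - m.m_filter) / m.m_pulp * 100.0


def summarize_reference(values: ReferenceSet | np.ndarray) -> SetStatistics:
    """n / min / max / mean / sample SD (n-1 denominator) of SCC values.

    A single value yields SD 0 with a degeneracy flag and a warning.
    """
    x = values.scc if isinstance(values, ReferenceSet) else np.asarray(
        values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot summarize an empty reference set")
    if x.size == 1:
        warnings.warn("single-value set: SD reported as 0", stacklevel=2)
        return SetStatistics(1, float(x[0]), float(x[0]), float(x[0]), 0.0,
                             sd_degenerate=True)
    return SetStatistics(int(x.size), float(x.min()), float(x.max()),
                         float(x.mean()), float(x.std(ddof=1)))


def anova_two_groups(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    """One-way ANOVA F statistic and p-value for two groups.

    With two groups F equals the square of the pooled-variance two-sample
    t statistic; used to check whether calibration and validation SCC
    distributions differ.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    f, p = stats.f_oneway(a, b)
    return {"F": float(f), "p": float(p)}
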