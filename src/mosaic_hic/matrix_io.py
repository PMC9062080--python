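"""Readers, writers and matrix transforms for binned intra-chromosomal Hi-C data.

The central containers are :class:`GenomicBinning` (a fixed-width binning of one
chromosome with a per-bin validity mask), :class:`ContactMatrix` (a symmetric
binned contact map tagged ``observed``, ``oe`` or ``correlation``) and
:class:`SignalTrack` (one real value per bin, NaN for missing data).

Coordinates are 0-based, half-open everywhere internally; BED output follows
BED conventions. Dense matrix files are whitespace-delimited, an optional
header line starting with ``#`` is allowed, and NaN entries mark invalid bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, ResourceError

log = logging.getLogger(__name__)

MATRIX_KINDS = ("observed", "oe", "correlation")

#: default fraction of missing track data above which a bin is masked
MISSING_TRACK_THRESHOLD = 0.5


@dataclass
class GenomicBinning:
    """Fixed-width binning of a single chromosome.

    Bins are 0-based, half-open, non-overlapping and contiguous from
    coordinate 0: bin ``i`` covers ``[i*bin_size, (i+1)*bin_size)``.
    """

    chrom: str
    bin_size: int
    n_bins: int
    valid: np.ndarray = field(default=None)  # bool per bin

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.valid is None:
            self.valid = np.ones(self.n_bins, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.valid) != self.n_bins:
            raise ValueError("valid mask length must equal n_bins")

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_size

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.bin_size

    def bin_of(self, position: int) -> int:
        """Bin index containing a bp position; -1 if out of range."""
        b = position // self.bin_size
        return int(b) if 0 <= b < self.n_bins else -1

    def copy(self) -> "GenomicBinning":
        return GenomicBinning(self.chrom, self.bin_size, self.n_bins, self.valid.copy())


@dataclass
class ContactMatrix:
    """Square symmetric binned contact matrix with a validity mask."""

    binning: GenomicBinning
    values: np.ndarray
    kind: str = "observed"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in MATRIX_KINDS:
            raise ValueError(f"kind must be one of {MATRIX_KINDS}")
        n = self.binning.n_bins
        if self.values.shape != (n, n):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match {n} bins"
            )

    @property
    def n_bins(self) -> int:
        return self.binning.n_bins

    @property
    def valid(self) -> np.ndarray:
        return self.binning.valid

    def valid_submatrix(self) -> np.ndarray:
        v = self.valid
        return self.values[np.ix_(v, v)]


@dataclass
class SignalTrack:
    """One aggregated signal value per bin; NaN marks missing data."""

    binning: GenomicBinning
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.binning.n_bins:
            raise ValueError("track length must match binning")


def _mask_from_matrix(values: np.ndarray) -> np.ndarray:
    """Invalid bins: all-NaN rows, residual non-finite entries, zero rows.

    An all-NaN row marks an unmappable bin; NaNs confined to such bins'
    columns do not invalidate their partners.
    """
    bad = ~np.isfinite(values)
    invalid = bad.all(axis=1)
    keep = ~invalid
    residual = bad[np.ix_(keep, keep)].any(axis=1)
    invalid[np.flatnonzero(keep)[residual]] = True
    row_sums = np.nansum(np.abs(values), axis=1)
    return ~invalid & (row_sums > 0)


def read_dense_matrix(path, chrom: str = "chr", bin_size: int = 100_000) -> ContactMatrix:
    """Read a whitespace-delimited square symmetric matrix file."""
    try:
        values = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"cannot parse dense matrix {path}: {exc}") from None
    if values.shape[0] != values.shape[1]:
        raise FormatError(
            f"dense matrix {path} is not square: {values.shape[0]}x{values.shape[1]}"
        )
    finite = np.isfinite(values) & np.isfinite(values.T)
    if np.nanmax(np.abs(np.where(finite, values - values.T, 0.0)), initial=0.0) > 1e-8:
        raise FormatError(f"dense matrix {path} is asymmetric beyond 1e-8")
    valid = _mask_from_matrix(values)
    values = np.nan_to_num(values, nan=0.0)
    values = (values + values.T) / 2.0
    binning = GenomicBinning(chrom, bin_size, values.shape[0], valid)
    return ContactMatrix(binning, values, kind="observed")


def _read_cooler_matrix(path, chrom: str, bin_size: int) -> ContactMatrix:
    try:
        import cooler  # noqa: F401  - optional dependency
    except ImportError:
        raise ResourceError(
            "reading .cool/.mcool files requires the optional 'cooler' package "
            "(pip install mosaic-hic[cool]); dense matrix files need no extra "
            "dependency"
        ) from None
    uri = str(path)
    if uri.endswith(".mcool"):
        uri = f"{uri}::/resolutions/{bin_size}"
    try:
        clr = cooler.Cooler(uri)
    except Exception as exc:
        raise ResourceError(f"cannot open cooler {uri}: {exc}") from None
    if clr.binsize != bin_size:
        raise ResourceError(
            f"{path} carries {clr.binsize} bp bins, requested {bin_size}"
        )
    if chrom not in clr.chromnames:
        raise ResourceError(f"chromosome {chrom} not in {path}")
    values = clr.matrix(balance=False).fetch(chrom).astype(float)
    valid = _mask_from_matrix(values)
    values = np.nan_to_num(values, nan=0.0)
    binning = GenomicBinning(chrom, bin_size, values.shape[0], valid)
    return ContactMatrix(binning, values, kind="observed")


def read_contact_matrix(path, chrom: str = "chr", bin_size: int = 100_000) -> ContactMatrix:
    """Read an intra-chromosomal contact matrix (cooler or dense text).

    Bins whose row sum is zero (or that contain non-finite entries) are
    marked invalid in the mask.
    """
    p = str(path)
    if p.endswith((".cool", ".mcool")):
        return _read_cooler_matrix(path, chrom, bin_size)
    return read_dense_matrix(path, chrom, bin_size)


def write_dense_matrix(path, m: ContactMatrix, header_lines=()) -> None:
    """Write a dense whitespace-delimited matrix; round-trips finite values."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        np.savetxt(fh, m.values, fmt="%.17g", delimiter="\t")


def observed_over_expected(m: ContactMatrix) -> ContactMatrix:
    """Observed/expected transform removing the distance-decay trend.

    The expected value at separation ``d`` is the arithmetic mean of the
    observed entries over all valid pairs ``|i - j| == d``; no smoothing is
    applied to the decay curve. Entries touching invalid bins, or whose
    expected value is zero, are set to 0.
    """
    if m.kind != "observed":
        raise ValueError("input must be an observed matrix")
    v = m.valid
    if not v.any():
        raise DegenerateInputError("all bins are invalid")
    n = m.n_bins
    vals = m.values
    oe = np.zeros_like(vals)
    vf = v.astype(float)
    for d in range(n):
        obs = np.diagonal(vals, offset=d)
        pair_ok = vf[: n - d] * vf[d:]
        n_ok = pair_ok.sum()
        if n_ok == 0:
            continue
        expected = float((obs * pair_ok).sum() / n_ok)
        if expected <= 0:
            continue
        idx = np.arange(n - d)
        ratio = np.where(pair_ok > 0, obs / expected, 0.0)
        oe[idx, idx + d] = ratio
        oe[idx + d, idx] = ratio
    return ContactMatrix(m.binning.copy(), oe, kind="oe")


def correlation_matrix(m: ContactMatrix) -> ContactMatrix:
    """Pearson correlation of matrix rows over valid bins.

    A constant row has undefined correlation; its bin is marked invalid and
    the correlations are recomputed without it.
    """
    if m.kind != "oe":
        raise ValueError("input must be an O/E matrix")
    valid = m.valid.copy()
    n = m.n_bins
    while True:
        idx = np.flatnonzero(valid)
        if idx.size < 2:
            raise DegenerateInputError("fewer than 2 valid bins for correlation")
        sub = m.values[np.ix_(idx, idx)]
        constant = sub.std(axis=1) == 0
        if not constant.any():
            break
        valid[idx[constant]] = False
    corr = np.corrcoef(sub)
    np.fill_diagonal(corr, 1.0)
    out = np.zeros((n, n))
    out[np.ix_(idx, idx)] = corr
    binning = m.binning.copy()
    binning.valid = valid
    return ContactMatrix(binning, out, kind="correlation")


def _read_interval_table(path, n_value_cols=1):
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3 + n_value_cols:
                raise FormatError(f"{path}:{ln}: expected ≥{3 + n_value_cols} columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from None
            rows.append((parts[0], start, end, *parts[3 : 3 + n_value_cols]))
    return rows


def read_track(
    path,
    binning: GenomicBinning,
    aggregation: str = "mean",
    min_coverage: float = 1.0 - MISSING_TRACK_THRESHOLD,
) -> SignalTrack:
    """Bin a bedGraph / 4-column scored BED into per-bin means.

    The per-bin value is the mean of the overlapping interval values weighted
    by overlap length. Bins with no covering data — or with more than
    ``1 - min_coverage`` of their length uncovered — are NaN (missing),
    never 0. Intervals on other chromosomes are skipped with a logged count.
    """
    if aggregation != "mean":
        raise ValueError("only mean aggregation is supported")
    rows = _read_interval_table(path, n_value_cols=1)
    weighted = np.zeros(binning.n_bins)
    covered = np.zeros(binning.n_bins)
    skipped = 0
    span = binning.n_bins * binning.bin_size
    for chrom, start, end, raw in rows:
        if chrom != binning.chrom:
            skipped += 1
            continue
        try:
            value = float(raw)
        except ValueError:
            raise FormatError(f"non-numeric score '{raw}' in {path}") from None
        start, end = max(start, 0), min(end, span)
        if end <= start:
            continue
        b0 = start // binning.bin_size
        b1 = (end - 1) // binning.bin_size
        for b in range(b0, b1 + 1):
            lo = max(start, b * binning.bin_size)
            hi = min(end, (b + 1) * binning.bin_size)
            weighted[b] += value * (hi - lo)
            covered[b] += hi - lo
    if skipped:
        log.info("read_track(%s): skipped %d intervals on other chromosomes", path, skipped)
    values = np.full(binning.n_bins, np.nan)
    has = covered >= min_coverage * binning.bin_size
    has &= covered > 0
    values[has] = weighted[has] / covered[has]
    return SignalTrack(binning.copy(), values, name=str(path))


def write_bedgraph(path, track: SignalTrack, header_lines=()) -> None:
    b = track.binning
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for i in range(b.n_bins):
            if np.isfinite(track.values[i]):
                fh.write(
                    f"{b.chrom}\t{i * b.bin_size}\t{(i + 1) * b.bin_size}\t{track.values[i]:.6g}\n"
                )


STATE_COLORS = {
    "A1": "227,26,28",
    "A2": "251,154,153",
    "B1": "31,120,180",
    "B2": "166,206,227",
    "A": "227,26,28",
    "B": "31,120,180",
}


def write_call_tsv(path, binning, states, ev1, ev2=None, header_lines=()) -> None:
    """Per-bin calls as TSV: chrom, start, end, state, EV1[, EV2]."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        cols = "chrom\tstart\tend\tstate\tEV1" + ("\tEV2" if ev2 is not None else "")
        fh.write(cols + "\n")
        for i in range(binning.n_bins):
            row = (
                f"{binning.chrom}\t{i * binning.bin_size}\t{(i + 1) * binning.bin_size}"
                f"\t{states[i]}\t{_fmt(ev1[i])}"
            )
            if ev2 is not None:
                row += f"\t{_fmt(ev2[i])}"
            fh.write(row + "\n")


def _fmt(x) -> str:
    return "NA" if not np.isfinite(x) else f"{x:.6g}"


def write_call_bed(path, binning, states, ev1, header_lines=()) -> None:
    """Per-bin calls as BED9 with an RGB colour per state."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for i in range(binning.n_bins):
            state = states[i]
            if state == "NA":
                continue
            start, end = i * binning.bin_size, (i + 1) * binning.bin_size
            score = ev1[i] if np.isfinite(ev1[i]) else 0.0
            rgb = STATE_COLORS.get(state, "128,128,128")
            fh.write(
                f"{binning.chrom}\t{start}\t{end}\t{state}\t{score:.6g}\t.\t{start}\t{end}\t{rgb}\n"
            )


def read_call_tsv(path) -> pd.DataFrame:
    """Read back a call TSV written by :func:`write_call_tsv`."""
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    required = {"chrom", "start", "end", "state"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: call TSV must have columns {sorted(required)}")
    for col in ("EV1", "EV2"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def read_bed_annotation(path) -> pd.DataFrame:
    """Read a BED file of labelled intervals (e.g. ChromHMM states)."""
    rows = _read_interval_table(path, n_value_cols=1)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
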