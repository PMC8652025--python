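"""Reading, writing and aligning genomic signal tracks.

A *signal track* assigns one real value to each of a set of non-overlapping
genomic intervals (bedGraph convention: 0-based, half-open coordinates).
Tracks here carry coverage-style signals — read counts, fold enrichment (FE)
over a control, or log Poisson p-values (LPPV) — and are strandless.

Replicated experiments are represented by a :class:`ReplicateSet`: two or
more tracks re-tiled onto the identical interval grid, which is the form the
mean–variance estimation machinery consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

SIGNAL_TYPES = ("raw", "fe", "lppv")

#: signal types for which values must be non-negative
_NONNEGATIVE_TYPES = ("raw", "fe")


@dataclass
class SignalTrack:
    """Per-interval numeric signal over a genome.

    Intervals are sorted by (chromosome, start) and are non-overlapping
    within each chromosome; ``end > start`` everywhere and all values are
    finite.  Use :meth:`from_arrays` to construct with sorting/validation.
    """

    chroms: np.ndarray   # dtype str/object, one entry per interval
    starts: np.ndarray   # int64, 0-based inclusive
    ends: np.ndarray     # int64, 0-based exclusive
    values: np.ndarray   # float64

    # -- construction -------------------------------------------------

    @classmethod
    def from_arrays(cls, chroms, starts, ends, values, validate: bool = True) -> "SignalTrack":
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        if not (len(chroms) == len(starts) == len(ends) == len(values)):
            raise ValidationError("chroms/starts/ends/values must have equal length")
        if len(starts):
            order = np.lexsort((starts, chroms.astype(str)))
            chroms, starts, ends, values = chroms[order], starts[order], ends[order], values[order]
        track = cls(chroms, starts, ends, values)
        if validate:
            track.validate()
        return track

    # -- invariants ---------------------------------------------------

    def validate(self) -> None:
        if len(self) == 0:
            return
        if np.any(self.ends <= self.starts):
            i = int(np.argmax(self.ends <= self.starts))
            raise ValidationError(
                f"interval end <= start at {self.chroms[i]}:{self.starts[i]}-{self.ends[i]}"
            )
        if not np.all(np.isfinite(self.values)):
            i = int(np.argmax(~np.isfinite(self.values)))
            raise ValidationError(
                f"non-finite value at {self.chroms[i]}:{self.starts[i]}-{self.ends[i]}"
            )
        same = self.chroms[1:] == self.chroms[:-1]
        overlap = same & (self.starts[1:] < self.ends[:-1])
        if np.any(overlap):
            i = int(np.argmax(overlap))
            raise ValidationError(
                f"overlapping intervals on {self.chroms[i]} near position {self.starts[i + 1]}"
            )

    # -- basic API ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def chrom_names(self) -> list[str]:
        """Chromosomes present, in sorted order."""
        return sorted(set(self.chroms.tolist()))

    def filter_chroms(self, chroms) -> "SignalTrack":
        keep = np.isin(self.chroms.astype(str), list(chroms))
        return SignalTrack(self.chroms[keep], self.starts[keep], self.ends[keep], self.values[keep])

    def with_values(self, values) -> "SignalTrack":
        """Same intervals, new values (used by transforms)."""
        values = np.asarray(values, dtype=np.float64)
        if values.shape != self.values.shape:
            raise ValidationError("replacement values must match interval count")
        return SignalTrack(self.chroms, self.starts, self.ends, values)

    def equal_grid(self, other: "SignalTrack") -> bool:
        return (
            len(self) == len(other)
            and bool(np.all(self.chroms == other.chroms))
            and bool(np.all(self.starts == other.starts))
            and bool(np.all(self.ends == other.ends))
        )


@dataclass
class ReplicateSet:
    """Two or more replicate tracks on an identical interval grid."""

    tracks: list
    signal_type: str
    dropped_bases: int = 0

    def __post_init__(self):
        if self.signal_type not in SIGNAL_TYPES:
            raise ValidationError(f"signal_type must be one of {SIGNAL_TYPES}")
        if len(self.tracks) < 2:
            raise ValidationError(
                "at least two replicates are required: the mean-variance "
                "relationship is learned from replicated data"
            )
        first = self.tracks[0]
        for t in self.tracks[1:]:
            if not first.equal_grid(t):
                raise ValidationError("replicate tracks are not on an identical interval grid")

    @property
    def m_replicates(self) -> int:
        return len(self.tracks)

    @property
    def n_positions(self) -> int:
        return len(self.tracks[0])

    @property
    def values(self) -> np.ndarray:
        """(M, N) matrix of replicate values."""
        return np.stack([t.values for t in self.tracks])

    def filter_chroms(self, chroms) -> "ReplicateSet":
        sub = [t.filter_chroms(chroms) for t in self.tracks]
        if len(sub[0]) == 0:
            raise ValidationError(f"no positions left after restricting to chromosomes {list(chroms)}")
        return replace(self, tracks=sub)


# ---------------------------------------------------------------------------
# bedGraph IO
# ---------------------------------------------------------------------------

def read_bedgraph(path, chroms=None) -> SignalTrack:
    """Read a bedGraph file into a :class:`SignalTrack`.

    Comment lines (``#``) and ``track``/``browser`` header lines are
    skipped.  Intervals are sorted; overlapping intervals or ``end <=
    start`` raise :class:`ValidationError`, malformed lines raise
    :class:`ParseError` with the line number.

    Parameters
    ----------
    path : str or Path
        File to read.
    chroms : iterable of str, optional
        If given, keep only intervals on these chromosomes.
    """
    cs, ss, es, vs = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(("track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, s_raw, e_raw, v_raw = parts
            try:
                start, end = int(s_raw), int(e_raw)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates {s_raw!r}, {e_raw!r}") from None
            try:
                value = float(v_raw)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric value {v_raw!r}") from None
            if not np.isfinite(value):
                raise ParseError(f"{path}:{lineno}: non-finite value {v_raw!r}")
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: interval end {end} <= start {start}")
            if chroms is not None and chrom not in chroms:
                continue
            cs.append(chrom)
            ss.append(start)
            es.append(end)
            vs.append(value)
    return SignalTrack.from_arrays(cs, ss, es, vs)


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a track as 4-column bedGraph (round-trips through
    :func:`read_bedgraph` to within 1e-10 relative on values)."""
    with open(path, "w") as fh:
        for chrom, start, end, value in zip(track.chroms, track.starts, track.ends, track.values):
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.10g}\n")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_replicates(tracks, signal_type: str) -> ReplicateSet:
    """Re-tile replicate tracks onto their common interval grid.

    The output grid is, per chromosome, the set of segments between all
    interval boundaries of all tracks (the finest grid present), restricted
    to the region covered by *every* track.  A coarser track's value is
    replicated into each sub-segment it spans.  Bases covered by only some
    tracks are dropped and counted.

    Raises
    ------
    ValidationError
        If fewer than two tracks, zero common coverage, non-finite values,
        or negative values for ``raw``/``fe`` signal types.
    """
    if len(tracks) < 2:
        raise ValidationError(
            "at least two replicates are required: the mean-variance "
            "relationship is learned from replicated data"
        )
    if signal_type not in SIGNAL_TYPES:
        raise ValidationError(f"signal_type must be one of {SIGNAL_TYPES}")
    for k, t in enumerate(tracks):
        if not np.all(np.isfinite(t.values)):
            raise ValidationError(f"replicate {k}: non-finite values")
        if signal_type in _NONNEGATIVE_TYPES and len(t) and t.values.min() < 0:
            raise ValidationError(
                f"replicate {k}: negative values are invalid for signal type {signal_type!r}"
            )

    m = len(tracks)
    all_chroms = sorted({c for t in tracks for c in t.chrom_names})
    out_chroms, out_starts, out_ends = [], [], []
    out_values = [[] for _ in range(m)]
    dropped = 0

    for chrom in all_chroms:
        subs = [t.filter_chroms([chrom]) for t in tracks]
        edges = np.unique(np.concatenate([np.concatenate([s.starts, s.ends]) for s in subs if len(s)]))
        if len(edges) < 2:
            continue
        seg_start, seg_end = edges[:-1], edges[1:]
        seg_len = seg_end - seg_start

        covered = np.zeros((m, len(seg_start)), dtype=bool)
        seg_values = np.zeros((m, len(seg_start)))
        for k, s in enumerate(subs):
            if len(s) == 0:
                continue
            idx = np.searchsorted(s.starts, seg_start, side="right") - 1
            ok = idx >= 0
            idx_c = np.clip(idx, 0, len(s) - 1)
            ok &= (s.starts[idx_c] <= seg_start) & (s.ends[idx_c] >= seg_end)
            covered[k] = ok
            seg_values[k] = np.where(ok, s.values[idx_c], 0.0)

        n_cov = covered.sum(axis=0)
        keep = n_cov == m
        dropped += int(seg_len[(n_cov > 0) & ~keep].sum())
        if not np.any(keep):
            continue
        out_chroms.append(np.full(int(keep.sum()), chrom, dtype=object))
        out_starts.append(seg_start[keep])
        out_ends.append(seg_end[keep])
        for k in range(m):
            out_values[k].append(seg_values[k][keep])

    if not out_starts:
        raise ValidationError("replicate tracks have zero common coverage")

    chroms_arr = np.concatenate(out_chroms)
    starts_arr = np.concatenate(out_starts)
    ends_arr = np.concatenate(out_ends)
    aligned = [
        SignalTrack(chroms_arr, starts_arr, ends_arr, np.concatenate(out_values[k]))
        for k in range(m)
    ]
    if dropped:
        logger.info("align_replicates: dropped %d bases not covered by all replicates", dropped)
    return ReplicateSet(aligned, signal_type, dropped_bases=dropped)
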