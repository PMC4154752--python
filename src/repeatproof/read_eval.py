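"""Synthetic long-read quality assessment.

Three related measurements live here:

* position-binned mismatch / insertion / deletion profiles along reads
  (distance from the read's 5' end as sequenced), the signature used to show
  that mismatches concentrate near read starts;
* per-scaffold depth of coverage from mapped reads;
* the residual-heterozygosity correction of the raw mismatch rate. Reads of
  an inbred line still carry segregating sites, which look like errors when
  mapped to the reference. The number of reference sites with at least one
  mismatch observation, M, decomposes as

      M     = L (e + h * pi)
      M_SNP = L (e p + h * pi)

  where L is the reference length aligned to, e the per-site error rate, h
  the residual heterozygosity, pi the population pairwise diversity, p the
  fraction of sites that are known SNPs, and M_SNP the subset of M
  overlapping known SNPs. Site-level error converts to per-read-base error
  by dividing by mean depth c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .align_io import ReadAlignment


@dataclass
class ErrorProfile:
    bin_width: int
    n_bins: int
    mismatch_events: np.ndarray = field(default=None)  # per bin
    insertion_events: np.ndarray = field(default=None)
    deletion_events: np.ndarray = field(default=None)
    aligned_bases: np.ndarray = field(default=None)  # per bin (M + X)

    def _rate(self, events: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(self.aligned_bases > 0, events / self.aligned_bases, 0.0)
        return r

    @property
    def mismatch_rate(self) -> np.ndarray:
        return self._rate(self.mismatch_events)

    @property
    def insertion_rate(self) -> np.ndarray:
        return self._rate(self.insertion_events)

    @property
    def deletion_rate(self) -> np.ndarray:
        return self._rate(self.deletion_events)

    def totals(self) -> dict[str, float]:
        denom = float(self.aligned_bases.sum())
        if denom == 0:
            return {"mismatch_rate": 0.0, "insertion_rate": 0.0, "deletion_rate": 0.0,
                    "aligned_bases": 0.0}
        return {
            "mismatch_rate": float(self.mismatch_events.sum()) / denom,
            "insertion_rate": float(self.insertion_events.sum()) / denom,
            "deletion_rate": float(self.deletion_events.sum()) / denom,
            "aligned_bases": denom,
        }

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_start": np.arange(self.n_bins) * self.bin_width,
                "mismatch_rate": self.mismatch_rate,
                "insertion_rate": self.insertion_rate,
                "deletion_rate": self.deletion_rate,
                "aligned_bases": self.aligned_bases,
            }
        )


def profile_errors(
    alignments: Iterable[ReadAlignment], bin_width: int = 100, mapq_min: int = 0
) -> ErrorProfile:
    """Accumulate error events and aligned-base denominators per read-position bin.

    Conventions: insertions contribute one event per inserted base at the
    run's read offset; deletions one event per deleted base, binned at the
    read offset immediately 5' of the deletion; aligned-base denominators
    count match + mismatch bases only.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    nb = 16
    mm = np.zeros(nb)
    ins = np.zeros(nb)
    dele = np.zeros(nb)
    denom = np.zeros(nb)

    def ensure(idx: int):
        nonlocal nb, mm, ins, dele, denom
        if idx >= nb:
            new_nb = nb
            while idx >= new_nb:
                new_nb *= 2
            mm = np.concatenate([mm, np.zeros(new_nb - nb)])
            ins = np.concatenate([ins, np.zeros(new_nb - nb)])
            dele = np.concatenate([dele, np.zeros(new_nb - nb)])
            denom = np.concatenate([denom, np.zeros(new_nb - nb)])
            nb = new_nb

    for aln in alignments:
        if aln.mapq < mapq_min:
            continue
        for run in aln.ops:
            b0 = run.read_offset // bin_width
            if run.op in "MX":
                # spread the run's bases over the bins it spans
                ensure((run.read_offset + run.length - 1) // bin_width)
                off = run.read_offset
                remaining = run.length
                while remaining > 0:
                    b = off // bin_width
                    take = min(remaining, (b + 1) * bin_width - off)
                    denom[b] += take
                    if run.op == "X":
                        mm[b] += take
                    off += take
                    remaining -= take
            elif run.op == "I":
                ensure((run.read_offset + run.length - 1) // bin_width)
                off = run.read_offset
                remaining = run.length
                while remaining > 0:
                    b = off // bin_width
                    take = min(remaining, (b + 1) * bin_width - off)
                    ins[b] += take
                    off += take
                    remaining -= take
            elif run.op == "D":
                ensure(b0)
                dele[b0] += run.length
    # trim to last non-empty bin
    used = max(
        int(np.max(np.nonzero(denom + mm + ins + dele)[0])) + 1
        if np.any(denom + mm + ins + dele)
        else 1,
        1,
    )
    return ErrorProfile(
        bin_width=bin_width,
        n_bins=used,
        mismatch_events=mm[:used],
        insertion_events=ins[:used],
        deletion_events=dele[:used],
        aligned_bases=denom[:used],
    )


@dataclass
class CoverageTrack:
    """Run-length encoded depth per scaffold."""

    # per scaffold: (breakpoints, depths) with depth[i] on [bp[i], bp[i+1])
    tracks: dict[str, tuple[np.ndarray, np.ndarray]]
    ref_lengths: dict[str, int]

    def mean_depth(self, ref_id: str) -> float:
        bp, d = self.tracks[ref_id]
        return float(np.sum(np.diff(bp) * d)) / self.ref_lengths[ref_id]

    def depth_at(self, ref_id: str, pos: int) -> int:
        bp, d = self.tracks[ref_id]
        i = int(np.searchsorted(bp, pos, side="right")) - 1
        return int(d[i])

    def zero_intervals(self, ref_id: str) -> list[tuple[int, int]]:
        bp, d = self.tracks[ref_id]
        return [
            (int(bp[i]), int(bp[i + 1])) for i in range(len(d)) if d[i] == 0
        ]

    def covered_intervals(self, ref_id: str, min_depth: int = 1) -> list[tuple[int, int]]:
        bp, d = self.tracks[ref_id]
        out = []
        for i in range(len(d)):
            if d[i] >= min_depth:
                if out and out[-1][1] == bp[i]:
                    out[-1] = (out[-1][0], int(bp[i + 1]))
                else:
                    out.append((int(bp[i]), int(bp[i + 1])))
        return out

    def genome_mean(self) -> float:
        tot = sum(
            float(np.sum(np.diff(bp) * d)) for bp, d in self.tracks.values()
        )
        return tot / sum(self.ref_lengths.values())


def depth_of_coverage(
    alignments: Iterable[ReadAlignment],
    ref_lengths: dict[str, int],
    mapq_min: int = 0,
):
    """Depth per scaffold from match/mismatch-consuming operations only.

    Returns (CoverageTrack, per-scaffold mean table).
    """
    import pandas as pd

    deltas: dict[str, dict[int, int]] = {r: {} for r in ref_lengths}
    for aln in alignments:
        if aln.mapq < mapq_min or aln.ref_id not in deltas:
            continue
        dd = deltas[aln.ref_id]
        for s, e in aln.ref_covered_intervals():
            dd[s] = dd.get(s, 0) + 1
            dd[e] = dd.get(e, 0) - 1
    tracks = {}
    rows = []
    for ref_id, L in sorted(ref_lengths.items()):
        dd = deltas[ref_id]
        pts = sorted(set([0, L]) | set(dd))
        pts = [p for p in pts if 0 <= p <= L]
        bp = np.array(pts, dtype=np.int64)
        depth = np.cumsum([dd.get(p, 0) for p in pts[:-1]])
        tracks[ref_id] = (bp, depth.astype(np.int64))
        mean = float(np.sum(np.diff(bp) * depth)) / L if L else 0.0
        rows.append({"ref_id": ref_id, "length": L, "mean_depth": mean})
    return CoverageTrack(tracks=tracks, ref_lengths=dict(ref_lengths)), pd.DataFrame(rows)


def mismatch_site_count(
    alignments: Iterable[ReadAlignment],
    snp_positions: dict[str, set[int]] | None = None,
    mapq_min: int = 0,
) -> tuple[int, int]:
    """Count reference sites with >=1 mismatch observation (M), and the subset
    overlapping known SNP positions (M_SNP). Sites, not events: a position hit
    by several mismatching reads counts once."""
    sites: dict[str, set[int]] = {}
    for aln in alignments:
        if aln.mapq < mapq_min:
            continue
        bucket = sites.setdefault(aln.ref_id, set())
        for op, s, e in aln.iter_ref_ops():
            if op == "X":
                bucket.update(range(s, e))
    M = sum(len(v) for v in sites.values())
    M_SNP = 0
    if snp_positions:
        for ref_id, v in sites.items():
            M_SNP += len(v & snp_positions.get(ref_id, set()))
    return M, M_SNP


@dataclass
class HetSolveInput:
    """Inputs of the error/heterozygosity decomposition (see module docstring)."""

    M: int
    L: int
    pi: float
    c: float
    M_SNP: int | None = None
    p: float | None = None
    h: float | None = None

    def __post_init__(self):
        if (self.M_SNP is None) == (self.h is None):
            raise ValueError("supply exactly one of M_SNP (with p) or h")
        if self.M_SNP is not None and self.p is None:
            raise ValueError("M_SNP requires p (fraction of sites that are known SNPs)")
        if not 0 <= self.M <= self.L:
            raise ValueError("need 0 <= M <= L")
        if self.M_SNP is not None and not 0 <= self.M_SNP <= self.M:
            raise ValueError("need 0 <= M_SNP <= M")
        if not 0 < self.pi < 1:
            raise ValueError("pi must be in (0, 1)")
        if self.p is not None and not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if self.c <= 0:
            raise ValueError("mean depth c must be positive")


def solve_error_rates(x: HetSolveInput) -> dict[str, float]:
    """Solve the mismatch-site decomposition for error rate and heterozygosity.

    With M_SNP: e_site = (M - M_SNP) / (L (1 - p)); h = (M/L - e_site) / pi.
    With h:     e_site = M/L - h*pi.
    Always:     e_read = e_site / c.

    Raises on a negative intermediate (model inconsistent with inputs).
    """
    if x.M == 0 and (x.M_SNP == 0 or x.h == 0 or x.h is None):
        return {"e_site": 0.0, "e_read": 0.0, "h": 0.0}
    if x.M_SNP is not None:
        e_site = (x.M - x.M_SNP) / (x.L * (1.0 - x.p))
        h = (x.M / x.L - e_site) / x.pi
    else:
        e_site = x.M / x.L - x.h * x.pi
        h = x.h
    if e_site < 0 or h < 0:
        raise ValueError(
            f"inconsistent inputs: e_site={e_site:.3g}, h={h:.3g} "
            "(heterozygosity term exceeds observed mismatch-site rate)"
        )
    return {"e_site": e_site, "e_read": e_site / x.c, "h": h}


def forward_mismatch_counts(
    e_site: float, h: float, L: int, pi: float, p: float
) -> tuple[float, float]:
    """Forward model of the decomposition — expected (M, M_SNP) given rates.

    Exact algebraic inverse of :func:`solve_error_rates`'s M_SNP branch when
    counts are left unrounded; tests round-trip through it.
    """
    M = L * (e_site + h * pi)
    M_SNP = L * (e_site * p + h * pi)
    return M, M_SNP
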