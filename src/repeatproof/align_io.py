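"""Readers and writers for the alignment and annotation formats the pipeline touches.

Internal convention: every coordinate is 0-based half-open on the forward
strand of its sequence. PAF and BED are already in that convention; GFF3 and
NUCmer ``show-coords`` tab output are 1-based inclusive and are converted at
the parse/write boundary, nowhere else.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

# ---------------------------------------------------------------------------
# Records


@dataclass
class AlignmentBlock:
    """One local contig-to-reference alignment.

    Reference and contig intervals are stored in forward orientation with a
    separate strand flag, so downstream interval arithmetic never needs to
    care about orientation.
    """

    contig_id: str
    contig_start: int
    contig_end: int
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str = "+"
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start:
            raise ValueError(
                f"block on {self.ref_id}: ref_end {self.ref_end} <= ref_start {self.ref_start}"
            )
        if self.contig_end <= self.contig_start:
            raise ValueError(f"block on {self.contig_id}: empty contig interval")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def aligned_length(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def score(self) -> float:
        return self.identity * self.aligned_length


@dataclass
class OpRun:
    """A run of identical alignment operations at a read offset.

    ``op`` is one of ``M`` (match), ``X`` (mismatch), ``I`` (insertion to the
    read), ``D`` (deletion from the read). ``read_offset`` is the distance of
    the run's first base from the read's 5' end as sequenced; for a deletion
    it is the offset of the read base immediately 5' of the deleted span.
    """

    op: str
    length: int
    read_offset: int


@dataclass
class ReadAlignment:
    read_id: str
    ref_id: str
    ref_start: int
    strand: str = "+"
    mapq: int = 60
    ops: list[OpRun] = field(default_factory=list)
    read_length: int = 0

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(r.length for r in self.ops if r.op in "MXD")

    def iter_ref_ops(self):
        """Yield (op, ref_start, ref_end) in reference order; insertions get a
        zero-length reference interval at their anchor point."""
        runs = self.ops if self.strand == "+" else list(reversed(self.ops))
        pos = self.ref_start
        for r in runs:
            if r.op in "MXD":
                yield r.op, pos, pos + r.length
                pos += r.length
            else:
                yield r.op, pos, pos

    def ref_covered_intervals(self) -> list[tuple[int, int]]:
        """Reference intervals consumed by match/mismatch runs (deletions
        advance the reference but contribute no coverage)."""
        runs = self.ops if self.strand == "+" else list(reversed(self.ops))
        out = []
        pos = self.ref_start
        for r in runs:
            if r.op in "MX":
                out.append((pos, pos + r.length))
                pos += r.length
            elif r.op == "D":
                pos += r.length
        return out


@dataclass
class Feature:
    """A gene or TE annotation on the reference (0-based half-open)."""

    feature_id: str
    ref_id: str
    start: int
    end: int
    strand: str = "+"
    feature_type: str = "gene"
    family: str | None = None
    divergence: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# PAF


def read_paf(path: str | Path) -> list[AlignmentBlock]:
    """Parse a minimal 12-column PAF into alignment blocks.

    Identity is residue matches / alignment block length (columns 10 and 11).
    A malformed line aborts the whole parse with its line number; no partial
    result is returned.
    """
    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected >=12 PAF columns, got {len(f)}")
            try:
                blocks.append(
                    AlignmentBlock(
                        contig_id=f[0],
                        contig_start=int(f[2]),
                        contig_end=int(f[3]),
                        strand=f[4],
                        ref_id=f[5],
                        ref_start=int(f[7]),
                        ref_end=int(f[8]),
                        identity=int(f[9]) / int(f[10]),
                    )
                )
            except (ValueError, ZeroDivisionError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed PAF line: {exc}") from exc
    return blocks


def write_paf(
    blocks: Iterable[AlignmentBlock],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
    ref_lengths: dict[str, int] | None = None,
) -> None:
    blocks = list(blocks)
    clens = dict(contig_lengths or {})
    rlens = dict(ref_lengths or {})
    for b in blocks:
        clens.setdefault(b.contig_id, 0)
        rlens.setdefault(b.ref_id, 0)
        clens[b.contig_id] = max(clens[b.contig_id], b.contig_end)
        rlens[b.ref_id] = max(rlens[b.ref_id], b.ref_end)
    with open(path, "w") as fh:
        for b in blocks:
            blen = b.aligned_length
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            b.contig_id, clens[b.contig_id], b.contig_start, b.contig_end,
                            b.strand,
                            b.ref_id, rlens[b.ref_id], b.ref_start, b.ref_end,
                            round(b.identity * blen), blen, 60,
                        ],
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# NUCmer show-coords tab output


def read_coords(path: str | Path) -> list[AlignmentBlock]:
    """Parse ``show-coords -T`` style tab output (1-based inclusive).

    Columns: S1 E1 S2 E2 LEN1 LEN2 %IDY [ref_id contig_id]. A reversed
    interval (start > end) on either axis is normalized to forward
    orientation with strand '-'.
    """
    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ValueError(f"{path}:{lineno}: expected >=7 coords columns")
            try:
                s1, e1, s2, e2 = (int(x) for x in f[:4])
                idy = float(f[6]) / 100.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coords line: {exc}") from exc
            ref_id = f[7] if len(f) > 7 else "ref"
            contig_id = f[8] if len(f) > 8 else "contig"
            strand = "+"
            if s1 > e1:
                s1, e1 = e1, s1
                strand = "-"
            if s2 > e2:
                s2, e2 = e2, s2
                strand = "-"
            blocks.append(
                AlignmentBlock(
                    contig_id=contig_id,
                    contig_start=s2 - 1,
                    contig_end=e2,
                    ref_id=ref_id,
                    ref_start=s1 - 1,
                    ref_end=e1,
                    strand=strand,
                    identity=idy,
                )
            )
    return blocks


# ---------------------------------------------------------------------------
# SAM / BAM and the simulator's tabular read alignments

_CONSUME_READ = set("MIS=X")
_CONSUME_REF = set("MDN=X")


def read_read_alignments(
    path: str | Path,
    reference: dict[str, str] | None = None,
) -> Iterator[ReadAlignment]:
    """Stream per-read operation runs from a SAM/BAM file.

    Mismatches are classified from the MD tag when present, otherwise from
    ``reference``. Unmapped records are skipped; the count of skipped records
    is available as the ``skipped_unmapped`` attribute on the generator after
    exhaustion via :func:`collect_read_alignments`.
    """
    yield from _iter_sam(path, reference)


def collect_read_alignments(
    path: str | Path, reference: dict[str, str] | None = None
) -> tuple[list[ReadAlignment], int]:
    """Eager variant of :func:`read_read_alignments`; returns (alignments, n_unmapped)."""
    alns = []
    skipped = 0
    for item in _iter_sam(path, reference, count_unmapped=True):
        if item is None:
            skipped += 1
        else:
            alns.append(item)
    return alns, skipped


def _iter_sam(path, reference, count_unmapped: bool = False):
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.cigartuples is None:
                    if count_unmapped:
                        yield None
                    continue
                yield _sam_record_to_alignment(rec, reference)
    finally:
        pysam.set_verbosity(save)


def _sam_record_to_alignment(rec, reference) -> ReadAlignment:
    query = rec.query_sequence
    if rec.has_tag("MD"):
        ref_seq = rec.get_reference_sequence().upper()
    elif reference is not None:
        ref_seq = reference[rec.reference_name][
            rec.reference_start : rec.reference_end
        ].upper()
    else:
        raise ValueError(
            f"record {rec.query_name}: no MD tag and no reference supplied; "
            "cannot classify matches vs mismatches"
        )
    # build per-base ops along the alignment (reference order), then RLE
    ops: list[tuple[str, int]] = []  # (op, length) reference-order runs
    qpos = 0
    rpos = 0
    for op, length in rec.cigartuples:
        code = "MIDNSHP=XB"[op]
        if code in "SH":
            if code == "S":
                qpos += length
            continue
        if code in "M=X":
            for i in range(length):
                q = query[qpos + i] if query else "N"
                r = ref_seq[rpos + i]
                _push(ops, "M" if q.upper() == r else "X")
            qpos += length
            rpos += length
        elif code == "I":
            _push(ops, "I", length)
            qpos += length
        elif code in "DN":
            _push(ops, "D", length)
            rpos += length
    strand = "-" if rec.is_reverse else "+"
    read_len = rec.infer_read_length() or qpos
    runs = _runs_with_offsets(ops, strand, read_len, leading_clip=_leading_clip(rec))
    return ReadAlignment(
        read_id=rec.query_name,
        ref_id=rec.reference_name,
        ref_start=rec.reference_start,
        strand=strand,
        mapq=rec.mapping_quality,
        ops=runs,
        read_length=read_len,
    )


def _push(ops: list[tuple[str, int]], op: str, length: int = 1) -> None:
    if ops and ops[-1][0] == op:
        ops[-1] = (op, ops[-1][1] + length)
    else:
        ops.append((op, length))


def _leading_clip(rec) -> int:
    ct = rec.cigartuples
    return ct[0][1] if ct and ct[0][0] in (4, 5) else 0


def _runs_with_offsets(
    ops: list[tuple[str, int]], strand: str, read_len: int, leading_clip: int = 0
) -> list[OpRun]:
    """Attach 5'-of-read offsets to reference-order runs and return them in
    read order (offsets strictly non-decreasing)."""
    runs = []
    # offset along the aligned portion of the read, in alignment (reference) order
    aln_off = 0
    for op, length in ops:
        runs.append((op, length, aln_off))
        if op in "MXI":
            aln_off += length
    aligned_read_len = aln_off
    out = []
    for op, length, off in runs:
        if strand == "+":
            read_off = leading_clip + off
            if op == "D":
                read_off = leading_clip + off - 1
        else:
            # as-sequenced offset of the run's first base (the run's 3'-most
            # base in reference orientation is its 5'-most as sequenced)
            clip3 = read_len - leading_clip - aligned_read_len
            if op == "D":
                read_off = clip3 + (aligned_read_len - off) - 1
            else:
                read_off = clip3 + aligned_read_len - off - length
        out.append(OpRun(op, length, max(read_off, 0)))
    if strand == "-":
        out.reverse()
    return out


TAB_HEADER = "read_id\tref_id\tref_start\tstrand\tmapq\tread_length\tops"


def write_tabular_alignments(alns: Iterable[ReadAlignment], path: str | Path) -> None:
    """The simulator's plain-text alignment table (one read per line)."""
    with open(path, "w") as fh:
        fh.write(TAB_HEADER + "\n")
        for a in alns:
            ops = ",".join(f"{r.op}{r.length}@{r.read_offset}" for r in a.ops)
            fh.write(
                f"{a.read_id}\t{a.ref_id}\t{a.ref_start}\t{a.strand}\t{a.mapq}\t{a.read_length}\t{ops}\n"
            )


def read_tabular_alignments(path: str | Path) -> list[ReadAlignment]:
    alns = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"{path}: missing tabular alignment header")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            runs = []
            if f[6]:
                for tok in f[6].split(","):
                    op = tok[0]
                    length, off = tok[1:].split("@")
                    runs.append(OpRun(op, int(length), int(off)))
            alns.append(
                ReadAlignment(
                    read_id=f[0], ref_id=f[1], ref_start=int(f[2]), strand=f[3],
                    mapq=int(f[4]), ops=runs, read_length=int(f[5]),
                )
            )
    return alns


# ---------------------------------------------------------------------------
# FASTA / GFF3 / BED / VCF helpers


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(features: Iterable[Feature], path: str | Path, source: str = "repeatproof") -> None:
    """Emit annotations as GFF3 (converting to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f.feature_id}"]
            if f.family is not None:
                attrs.append(f"family={f.family}")
            if f.divergence is not None:
                attrs.append(f"divergence={f.divergence:.6f}")
            ftype = "gene" if f.feature_type == "gene" else "transposable_element"
            fh.write(
                "\t".join(
                    [
                        f.ref_id, source, ftype,
                        str(f.start + 1), str(f.end), ".", f.strand, ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            feats.append(
                Feature(
                    feature_id=attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"),
                    ref_id=f[0],
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    strand=f[6] if f[6] in "+-" else "+",
                    feature_type="gene" if f[2] == "gene" else "TE",
                    family=attrs.get("family"),
                    divergence=float(attrs["divergence"]) if "divergence" in attrs else None,
                )
            )
    return feats


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ref_id, s, e in intervals:
            fh.write(f"{ref_id}\t{s}\t{e}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_vcf_sites(
    sites: Iterable[tuple[str, int, str, str]], path: str | Path
) -> None:
    """Sites-only VCF of known heterozygous positions (ref_id, pos0, ref, alt)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for ref_id, pos, ref, alt in sites:
            fh.write(f"{ref_id}\t{pos + 1}\t.\t{ref}\t{alt}\t.\t.\t.\n")


def read_vcf_sites(path: str | Path) -> list[tuple[str, int, str, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]) - 1, f[3], f[4]))
    return out


def blocks_to_dataframe(blocks: Iterable[AlignmentBlock]):
    import pandas as pd

    return pd.DataFrame([dataclasses.asdict(b) for b in blocks])
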