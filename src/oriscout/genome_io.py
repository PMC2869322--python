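"""Genome, annotation, site-list and PWM I/O, plus intergene extraction.

Coordinate conventions: everything is 0-based, half-open internally and in
BED output; GFF3 input (1-based, inclusive) is converted on read. Intergenic
regions are the maximal intervals of a chromosome not covered by any
filtered feature (by default genes, LTRs and assembly gaps — tRNAs are
deliberately not filtered, so they remain inside intergenes and can be
tested for ARS co-localization).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .motif import PWM

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceRecord",
    "Feature",
    "IntergenicRegion",
    "RegionMask",
    "Site",
    "CandidateRecord",
    "STATUSES",
    "load_genome",
    "load_features",
    "extract_intergenes",
    "read_pwm",
    "write_pwm",
    "read_sites",
    "write_sites",
    "read_candidates",
    "write_candidates",
    "read_mask",
]

STATUSES = ("functional", "nonfunctional", "unavailable", "pending")

_VALID = set("ACGTN")


@dataclass
class SequenceRecord:
    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str = "."
    ftype: str = "other"
    name: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad feature interval [{self.start},{self.end})")


@dataclass
class IntergenicRegion:
    chrom: str
    start: int
    end: int
    left_gene: Feature | None = None
    right_gene: Feature | None = None
    contains_trna: bool = False
    terminal: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Site:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "+"


@dataclass
class CandidateRecord:
    """One row of the predict-and-verify ledger."""

    chrom: str
    acs_start: int
    acs_end: int
    strand: str
    score: float
    iteration: int = 0
    status: str = "pending"
    flank: int = 200
    in_coding: bool = False

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"invalid status {self.status!r}")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    @property
    def center(self) -> int:
        return (self.acs_start + self.acs_end) // 2


# ---------------------------------------------------------------------------
# genome / features
# ---------------------------------------------------------------------------


def load_genome(path) -> dict[str, SequenceRecord]:
    """Load a FASTA genome; sequences uppercased, ambiguity codes other
    than N mapped to N (count logged). Duplicate ids or an empty file are
    errors."""
    records: dict[str, SequenceRecord] = {}
    n_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = [ch for ch in set(seq) if ch not in _VALID]
        if bad:
            for ch in bad:
                n_mapped += seq.count(ch)
                seq = seq.replace(ch, "N")
        records[rec.id] = SequenceRecord(rec.id, seq)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if n_mapped:
        logger.warning("mapped %d ambiguous IUPAC bases to N", n_mapped)
    return records


def load_features(path) -> list[Feature]:
    """Read features from GFF3 (.gff/.gff3; 1-based inclusive, converted)
    or a tab-separated table: chrom, start, end, ftype[, strand, name] with
    0-based half-open coordinates."""
    path = Path(path)
    feats: list[Feature] = []
    if path.suffix.lower() in {".gff", ".gff3"}:
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique")
        for f in db.all_features():
            name = f.attributes.get("Name", f.attributes.get("ID", [""]))[0]
            feats.append(Feature(
                chrom=f.seqid, start=f.start - 1, end=f.end,
                strand=f.strand or ".", ftype=f.featuretype, name=name))
    else:
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}:{ln}: expected >=4 columns")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError as e:
                    raise ValueError(f"{path}:{ln}: malformed coordinate") from e
                strand = parts[4] if len(parts) > 4 else "."
                name = parts[5] if len(parts) > 5 else ""
                feats.append(Feature(parts[0], start, end, strand, parts[3], name))
    return feats


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivals:
        return []
    ivals = sorted(ivals)
    out = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def extract_intergenes(
    genome: dict[str, SequenceRecord],
    features: list[Feature],
    filter_types: set[str] = frozenset({"gene", "LTR", "gap"}),
) -> list[IntergenicRegion]:
    """Maximal intervals not covered by any filtered feature.

    Overlapping/abutting filtered features are merged before complementing;
    zero-length intergenes are dropped. Each region is annotated with its
    nearest filtered flanking features, whether it contains a tRNA feature,
    and whether it touches a chromosome end (terminal).
    """
    if not filter_types:
        raise ValueError("filter_types must be nonempty")
    by_chrom: dict[str, list[Feature]] = {}
    trnas: dict[str, list[Feature]] = {}
    for f in features:
        if f.chrom in genome and f.end > genome[f.chrom].length:
            raise ValueError(f"feature {f} beyond chromosome end")
        if f.ftype in filter_types:
            by_chrom.setdefault(f.chrom, []).append(f)
        if f.ftype == "tRNA":
            trnas.setdefault(f.chrom, []).append(f)
    regions: list[IntergenicRegion] = []
    for chrom in sorted(genome):
        L = genome[chrom].length
        feats = sorted(by_chrom.get(chrom, []), key=lambda f: (f.start, f.end))
        merged = _merge_intervals([(f.start, f.end) for f in feats])
        bounds = [0] + [x for iv in merged for x in iv] + [L]
        for i in range(0, len(bounds), 2):
            s, e = bounds[i], bounds[i + 1]
            if e <= s:
                continue
            left = _nearest_left(feats, s)
            right = _nearest_right(feats, e)
            has_trna = any(t.start < e and t.end > s for t in trnas.get(chrom, []))
            regions.append(IntergenicRegion(
                chrom, s, e, left_gene=left, right_gene=right,
                contains_trna=has_trna,
                terminal=(s == 0 or e == L)))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _nearest_left(feats: list[Feature], pos: int) -> Feature | None:
    best = None
    for f in feats:
        if f.end <= pos and (best is None or f.end > best.end):
            best = f
    return best


def _nearest_right(feats: list[Feature], pos: int) -> Feature | None:
    best = None
    for f in feats:
        if f.start >= pos and (best is None or f.start < best.start):
            best = f
    return best


class RegionMask:
    """Merged, sorted set of excluded intervals (e.g. repetitive telomeric
    regions that the prediction process should ignore)."""

    def __init__(self, intervals=()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            if e <= s:
                raise ValueError(f"bad mask interval [{s},{e})")
            by_chrom.setdefault(chrom, []).append((s, e))
        self._ivals = {c: _merge_intervals(v) for c, v in by_chrom.items()}

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        return self._ivals.get(chrom, [])

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return any(s < end and e > start for s, e in self._ivals.get(chrom, []))

    def __len__(self) -> int:
        return sum(len(v) for v in self._ivals.values())


def read_mask(path) -> RegionMask:
    sites = read_sites(path)
    return RegionMask((s.chrom, s.start, s.end) for s in sites)


# ---------------------------------------------------------------------------
# PWM text format: 4 x w matrix, rows A/C/G/T, tab-delimited, '#'-comments
# ---------------------------------------------------------------------------


def write_pwm(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# PWM w={pwm.width} pseudocount={pwm.pseudocount} "
                 f"n_sites={pwm.n_sites}\n")
        if pwm.provenance:
            fh.write(f"# {pwm.provenance}\n")
        fh.write("# rows: A C G T\n")
        for b in range(4):
            fh.write("\t".join(repr(float(x)) for x in pwm.probs[:, b]) + "\n")


def read_pwm(path, pseudocount: float = 0.01) -> PWM:
    """Read a whitespace-delimited 4 x w (or w x 4 with more than 4
    columns) matrix of probabilities or counts. Counts are normalized per
    column with the given pseudocount; the total is recorded in the
    provenance."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([float(x) for x in line.split()])
    mat = np.array(rows, dtype=float)
    if mat.ndim != 2:
        raise ValueError("PWM file is not a rectangular matrix")
    if mat.shape[0] != 4 and mat.shape[1] == 4:
        mat = mat.T
    if mat.shape[0] != 4:
        raise ValueError("PWM matrix must have 4 rows (A,C,G,T) or 4 columns")
    if np.any(mat < 0):
        raise ValueError("negative PWM entries")
    mat = mat.T  # -> (w, 4)
    sums = mat.sum(axis=1)
    if np.any(sums == 0):
        raise ValueError("PWM column with zero total")
    if np.allclose(sums, 1.0, atol=1e-6):
        probs = mat / sums[:, None]
        prov = f"read from {path}"
    else:
        probs = (mat + pseudocount) / (sums + 4 * pseudocount)[:, None]
        prov = f"read counts from {path}; column totals {sums.tolist()}"
    return PWM(probs, pseudocount=pseudocount, provenance=prov)


# ---------------------------------------------------------------------------
# site lists (BED6 / CSV) and the candidate ledger (CSV)
# ---------------------------------------------------------------------------


def read_sites(path) -> list[Site]:
    """Read sites from BED (0-based half-open) or CSV with columns
    chrom,start,end[,name,score,strand]."""
    path = Path(path)
    sites: list[Site] = []
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        for _, r in df.iterrows():
            sites.append(Site(
                str(r["chrom"]), int(r["start"]), int(r["end"]),
                str(r.get("name", ".")), float(r.get("score", 0.0)),
                str(r.get("strand", "+"))))
        return sites
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            if len(p) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >=3 columns")
            try:
                start, end = int(p[1]), int(p[2])
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: malformed coordinate") from e
            if end <= start:
                raise ValueError(f"{path}:{ln}: empty/negative interval")
            name = p[3] if len(p) > 3 else "."
            score = float(p[4]) if len(p) > 4 and p[4] != "." else 0.0
            strand = p[5] if len(p) > 5 else "+"
            sites.append(Site(p[0], start, end, name, score, strand))
    return sites


def write_sites(sites, path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.name}\t{s.score:g}\t"
                     f"{s.strand}\n")


_CAND_COLS = ["chrom", "acs_start", "acs_end", "strand", "score",
              "iteration", "status", "flank", "in_coding"]


def write_candidates(records, path) -> None:
    with open(path, "w", newline="") as fh:
        wtr = csv.writer(fh)
        wtr.writerow(_CAND_COLS)
        for r in records:
            wtr.writerow([r.chrom, r.acs_start, r.acs_end, r.strand,
                          f"{r.score:.2f}", r.iteration, r.status, r.flank,
                          int(r.in_coding)])


def read_candidates(path) -> list[CandidateRecord]:
    df = pd.read_csv(path)
    out = []
    for i, r in df.iterrows():
        status = str(r["status"])
        if status not in STATUSES:
            raise ValueError(f"{path}: line {i + 2}: invalid status {status!r}")
        out.append(CandidateRecord(
            chrom=str(r["chrom"]), acs_start=int(r["acs_start"]),
            acs_end=int(r["acs_end"]), strand=str(r["strand"]),
            score=float(r["score"]), iteration=int(r.get("iteration", 0)),
            status=status, flank=int(r.get("flank", 200)),
            in_coding=bool(r.get("in_coding", False))))
    return out
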