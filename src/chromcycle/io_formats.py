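"""Standard-format I/O and the internal coordinate convention.

Everything internal is 0-based, half-open ``[start, end)``.  GFF3 (1-based,
closed) and BED/bedGraph (0-based, half-open) are converted at the boundary.
TSS and TES are strand-aware *point* coordinates on the half-open boundary
lattice: for a ``+`` gene the TSS is ``interval.start``, for a ``-`` gene it
is ``interval.end``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gffutils
import numpy as np
import pandas as pd

GENERATIONS = ("sp", "ga")  # sporophyte, gametophyte


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    """Genomic interval, 0-based half-open."""

    scaffold: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        if self.scaffold != other.scaffold:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to_point(self, point: int) -> int:
        """bp distance from a point coordinate to this interval (0 inside)."""
        return max(self.start - point, point - self.end, 0)


@dataclass(frozen=True)
class Scaffold:
    name: str
    length: int

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"scaffold {self.name} has non-positive length")


@dataclass(frozen=True)
class Gene:
    id: str
    interval: Interval
    strand: str
    exons: tuple[Interval, ...]
    biotype: str = "protein_coding"

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tes(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start

    @property
    def scaffold(self) -> str:
        return self.interval.scaffold

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def exon_count(self) -> int:
        return len(self.exons)


@dataclass
class GenomeAnnotation:
    """Scaffolds, genes and transposon intervals; the coordinate backbone."""

    scaffolds: dict[str, int]            # name -> length, insertion-ordered
    genes: list[Gene] = field(default_factory=list)
    tes: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        self.genes = sorted(
            self.genes, key=lambda g: (g.scaffold, g.interval.start, g.interval.end)
        )
        self.tes = sorted(self.tes, key=lambda t: (t.scaffold, t.start, t.end))
        for g in self.genes:
            if g.scaffold not in self.scaffolds:
                raise ValueError(f"gene {g.id} on undeclared scaffold {g.scaffold}")
            if g.interval.end > self.scaffolds[g.scaffold]:
                raise ValueError(f"gene {g.id} extends past scaffold end")
        self._by_id = {g.id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene ids in annotation")

    @property
    def genome_length(self) -> int:
        return sum(self.scaffolds.values())

    def gene(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def genes_on(self, scaffold: str) -> list[Gene]:
        return [g for g in self.genes if g.scaffold == scaffold]


@dataclass
class SignalTrack:
    """Fixed-bin coverage (raw counts) for one mark/generation/replicate.

    ``values[scaffold]`` has ``ceil(length / bin_size)`` entries; the final
    bin may be narrower than ``bin_size``.  ``library_size`` is the total raw
    count mass; ``normalized`` rescales to counts per million.
    """

    bin_size: int
    scaffolds: dict[str, int]
    values: dict[str, np.ndarray]
    mark: str = ""
    generation: str = ""
    replicate: int = 0

    def __post_init__(self):
        for name, length in self.scaffolds.items():
            n = math.ceil(length / self.bin_size)
            if name not in self.values:
                self.values[name] = np.zeros(n)
            elif len(self.values[name]) != n:
                raise ValueError(f"bin array length mismatch on {name}")

    def bin_widths(self, scaffold: str) -> np.ndarray:
        length = self.scaffolds[scaffold]
        n = len(self.values[scaffold])
        w = np.full(n, self.bin_size, dtype=float)
        w[-1] = length - (n - 1) * self.bin_size
        return w

    @property
    def library_size(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def normalized(self, scaffold: str) -> np.ndarray:
        lib = self.library_size
        if lib == 0:
            return np.zeros_like(self.values[scaffold])
        return self.values[scaffold] * (1e6 / lib)

    def value_at(self, scaffold: str, pos: int, norm: bool = True) -> float:
        arr = self.normalized(scaffold) if norm else self.values[scaffold]
        i = min(pos // self.bin_size, len(arr) - 1)
        return float(arr[i])

    def mean_in(self, scaffold: str, start: int, end: int, norm: bool = True) -> float:
        """Mean signal over [start, end), length-weighted across bins."""
        arr = self.normalized(scaffold) if norm else self.values[scaffold]
        length = self.scaffolds[scaffold]
        start, end = max(0, start), min(length, end)
        if end <= start:
            return 0.0
        i0, i1 = start // self.bin_size, (end - 1) // self.bin_size
        total = 0.0
        for i in range(i0, i1 + 1):
            b0, b1 = i * self.bin_size, min((i + 1) * self.bin_size, length)
            total += arr[i] * (min(end, b1) - max(start, b0))
        return total / (end - start)


@dataclass
class ExpressionTable:
    """Per-gene TPM across samples, with optional differential-expression
    fields (log2fc of sporophyte over gametophyte, pvalue, padj)."""

    tpm: pd.DataFrame                       # index gene_id, columns samples
    generations: dict[str, str]             # sample -> 'sp' | 'ga'
    de: pd.DataFrame | None = None          # index gene_id: log2fc, pvalue, padj
    dropped: int = 0                        # ids absent from the annotation

    def samples_of(self, generation: str) -> list[str]:
        return [s for s, g in self.generations.items() if g == generation]

    def mean_tpm(self, generation: str) -> pd.Series:
        return self.tpm[self.samples_of(generation)].mean(axis=1)

    @property
    def has_de(self) -> bool:
        return self.de is not None and len(self.de) > 0


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------

def read_annotation(path) -> GenomeAnnotation:
    """Read a GFF3 annotation (gene/mRNA/exon) into internal coordinates.

    Scaffold lengths come from ``##sequence-region`` directives; the biotype
    comes from a ``biotype`` / ``gene_biotype`` attribute (default
    protein_coding).
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    scaffolds: dict[str, int] = {}
    for d in db.directives:
        parts = d.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            scaffolds[parts[1]] = int(parts[3])

    genes, tes = [], []
    for f in db.features_of_type("gene", order_by=("seqid", "start")):
        if f.seqid not in scaffolds:
            raise ValueError(
                f"scaffold {f.seqid} of gene {f.id} has no ##sequence-region declaration"
            )
        giv = Interval(f.seqid, f.start - 1, f.end, f.strand)
        exons = []
        for e in db.children(f, featuretype="exon", order_by="start"):
            eiv = Interval(e.seqid, e.start - 1, e.end, e.strand)
            if eiv.start < giv.start or eiv.end > giv.end:
                raise ValueError(f"exon outside gene span for gene {f.id}")
            exons.append(eiv)
        if not exons:  # single-exon gene without explicit exon rows
            exons = [giv]
        if f.strand == "-":
            exons = exons[::-1]  # 5' -> 3'
        biotype = (f.attributes.get("biotype") or f.attributes.get("gene_biotype")
                   or ["protein_coding"])[0]
        genes.append(Gene(f.id, giv, f.strand, tuple(exons), biotype))
    for f in db.features_of_type(("transposable_element", "repeat_region")):
        tes.append(Interval(f.seqid, f.start - 1, f.end))
    return GenomeAnnotation(scaffolds, genes, tes)


def write_annotation(annotation: GenomeAnnotation, path) -> None:
    """Write the annotation back to GFF3 (gene/mRNA/exon rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in annotation.scaffolds.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in annotation.genes:
            s, e = g.interval.start + 1, g.interval.end
            fh.write(
                f"{g.scaffold}\tchromcycle\tgene\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.id};biotype={g.biotype}\n"
            )
            fh.write(
                f"{g.scaffold}\tchromcycle\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.id}.t1;Parent={g.id}\n"
            )
            exons = g.exons if g.strand == "+" else g.exons[::-1]
            for i, ex in enumerate(exons, 1):
                fh.write(
                    f"{g.scaffold}\tchromcycle\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\tID={g.id}.e{i};Parent={g.id}.t1\n"
                )


# ---------------------------------------------------------------------------
# BED / broadPeak intervals
# ---------------------------------------------------------------------------

def write_intervals(items, path, dialect: str = "bed") -> None:
    """Write scored intervals as BED6 or ENCODE broadPeak.

    ``items`` is an iterable of ``Interval`` or of objects with ``.interval``
    and ``.score``.  Scores are scaled into the integer BED range [0, 1000];
    output order is (scaffold, start, end), deterministic.
    """
    if dialect not in ("bed", "broadpeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    for it in items:
        iv = it.interval if hasattr(it, "interval") else it
        score = float(getattr(it, "score", 0.0))
        rows.append((iv.scaffold, iv.start, iv.end, iv.strand, score))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    smax = max((r[4] for r in rows), default=0.0)
    with open(path, "w") as fh:
        for i, (scaf, s, e, strand, score) in enumerate(rows):
            bedscore = int(round(1000 * score / smax)) if smax > 0 else 0
            name = f"item_{i + 1}"
            if dialect == "bed":
                fh.write(f"{scaf}\t{s}\t{e}\t{name}\t{bedscore}\t{strand}\n")
            else:
                fh.write(
                    f"{scaf}\t{s}\t{e}\t{name}\t{bedscore}\t{strand}\t"
                    f"{score:.6g}\t-1\t-1\n"
                )


def read_intervals(path) -> list[Interval]:
    """Read a BED3+ file into Intervals (strand from column 6 if present)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            strand = parts[5] if len(parts) > 5 else "."
            out.append(Interval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------

def read_track(path, bin_size: int, scaffolds: dict[str, int], *,
               mark: str = "", generation: str = "", replicate: int = 0) -> SignalTrack:
    """Read a sorted, non-overlapping bedGraph into a fixed-bin track.

    Values are rebinned by length-weighted mean; uncovered gaps are zero.
    """
    track = SignalTrack(bin_size, dict(scaffolds), {}, mark, generation, replicate)
    mass = {name: np.zeros_like(v) for name, v in track.values.items()}
    prev = None  # (scaffold, end)
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            scaf, s, e, v = line.split()[:4]
            s, e, v = int(s), int(e), float(v)
            if scaf not in scaffolds:
                raise ValueError(f"unknown scaffold {scaf} at line {lineno}")
            if prev is not None and prev[0] == scaf and s < prev[1]:
                raise ValueError(f"overlapping or unsorted records at line {lineno}")
            if prev is not None and prev[0] != scaf and scaf in seen:
                raise ValueError(f"scaffold blocks not contiguous at line {lineno}")
            seen.add(scaf)
            prev = (scaf, e)
            e = min(e, scaffolds[scaf])
            i0, i1 = s // bin_size, (e - 1) // bin_size
            m = mass[scaf]
            for i in range(i0, i1 + 1):
                b0, b1 = i * bin_size, min((i + 1) * bin_size, scaffolds[scaf])
                m[i] += v * (min(e, b1) - max(s, b0))
    for name in track.values:
        track.values[name] = mass[name] / track.bin_widths(name)
    return track


def write_track(track: SignalTrack, path, norm: bool = False) -> None:
    """Write a track as bedGraph, merging runs of equal values."""
    with open(path, "w") as fh:
        for name in track.scaffolds:
            arr = track.normalized(name) if norm else track.values[name]
            length = track.scaffolds[name]
            run_start, run_val = 0, arr[0] if len(arr) else 0.0
            for i in range(1, len(arr)):
                if arr[i] != run_val:
                    fh.write(f"{name}\t{run_start}\t{i * track.bin_size}\t{run_val:.6g}\n")
                    run_start, run_val = i * track.bin_size, arr[i]
            if len(arr):
                fh.write(f"{name}\t{run_start}\t{length}\t{run_val:.6g}\n")


# ---------------------------------------------------------------------------
# expression / DE tables
# ---------------------------------------------------------------------------

def write_expression(expr: ExpressionTable, path) -> None:
    df = expr.tpm.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def write_de(de: pd.DataFrame, path) -> None:
    df = de.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.8g")


def load_tables(expression_path, de_path, annotation: GenomeAnnotation,
                generations: dict[str, str] | None = None) -> ExpressionTable:
    """Load TPM and (optionally) DE tables, restricted to annotated genes.

    Sample generations default to a ``sp``/``ga`` prefix convention on the
    column names.  Genes absent from the annotation are dropped and counted.
    """
    tpm = pd.read_csv(expression_path, sep="\t", index_col="gene_id")
    if tpm.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression table")
    for col in tpm.columns:
        if not pd.api.types.is_numeric_dtype(tpm[col]):
            bad = tpm.index[pd.to_numeric(tpm[col], errors="coerce").isna()][0]
            raise ValueError(f"non-numeric expression value for gene {bad}")
    known = set(annotation.gene_ids)
    dropped = int((~tpm.index.isin(known)).sum())
    tpm = tpm.loc[tpm.index.isin(known)]
    if generations is None:
        generations = {c: ("sp" if c.startswith("sp") else "ga") for c in tpm.columns}
    de = None
    if de_path is not None:
        de = pd.read_csv(de_path, sep="\t", index_col="gene_id", na_values=["."])
        if de.index.duplicated().any():
            raise ValueError("duplicate gene ids in DE table")
        if len(de) == 0:
            de = None
        else:
            de = de.loc[de.index.isin(known)]
    return ExpressionTable(tpm, generations, de, dropped)
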