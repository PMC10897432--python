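"""Domain types, coordinate conventions and file I/O for the pipeline.

All internal coordinates are 0-based half-open; the only conversion happens
at the GFF3 boundary (GFF3 is 1-based, closed). Strand is ``"+"`` or ``"-"``.
For a gene on the plus strand the TSS is ``start`` and the TTS is ``end - 1``;
on the minus strand the TSS is ``end - 1`` and the TTS is ``start``.

Strand-specific signal is carried as one value per base of per-base 5' read
starts (raw counts) or normalized signal.  Minus-strand values are stored as
non-negative magnitudes; strand identity is carried by the file (one bedGraph
per strand), mirroring how strand-split coverage tracks are distributed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParseError",
    "StructuralError",
    "GeneModel",
    "TranscriptModel",
    "GenomeAnnotation",
    "TssPeak",
    "AcrPeak",
    "TranscriptCandidate",
    "ExpressionMatrix",
    "SignalTrack",
    "AnalysisParameters",
    "TSS_CATEGORIES",
    "LNCRNA_BIOTYPES",
    "SMALL_RNA_BIOTYPES",
    "oriented_window",
    "read_gff3",
    "read_bedgraph_pair",
    "write_bedgraph_pair",
    "read_bed",
    "write_bed",
    "read_matrix",
    "write_matrix",
    "read_de_table",
    "write_de_table",
]


class ParseError(ValueError):
    """A malformed record in an input file (message names the line)."""


class StructuralError(ValueError):
    """Structurally inconsistent input (e.g. a child feature with no parent)."""


# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

#: Annotation biotypes treated as long non-coding when a TSS is assigned to them.
LNCRNA_BIOTYPES = frozenset(
    {
        "antisense_long_non_coding_rna",
        "antisense_rna",
        "long_noncoding_rna",
        "novel_transcribed_region",
        "other_rna",
        "pseudogene",
        "transposable_element_gene",
    }
)

#: Annotation biotypes treated as small/structural non-coding RNA.
SMALL_RNA_BIOTYPES = frozenset(
    {"miRNA", "pre_trna", "small_nuclear_rna", "small_nucleolar_rna"}
)

#: The five final TSS categories plus the pre-annotation placeholder.
TSS_CATEGORIES = (
    "mRNA",
    "lncRNA",
    "otherNcRNA",
    "putativeLncRNA",
    "unstable",
    "unassigned",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TranscriptModel:
    tx_id: str
    start: int
    end: int
    five_prime_utr_end: Optional[int] = None  # 0-based, exclusive bound of the 5' UTR


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    chromosomes: list[tuple[str, int]]
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise StructuralError(f"duplicate gene id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom in lengths and not (0 <= g.start and g.end <= lengths[g.chrom]):
                raise StructuralError(
                    f"gene {g.gene_id} [{g.start},{g.end}) outside {g.chrom} "
                    f"[0,{lengths[g.chrom]})"
                )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


@dataclass
class TssPeak:
    peak_id: str
    chrom: str
    start: int
    end: int
    strand: str
    summit: Optional[int] = None
    width80: Optional[int] = None
    category: str = "unassigned"
    assigned_gene: Optional[str] = None
    expression: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(f"peak {self.peak_id}: summit outside interval")
        if self.category not in TSS_CATEGORIES:
            raise ValueError(f"peak {self.peak_id}: unknown category {self.category!r}")

    def __eq__(self, other: object) -> bool:  # expression compared by value
        if not isinstance(other, TssPeak):
            return NotImplemented
        if (self.expression is None) != (other.expression is None):
            return False
        expr_eq = (
            self.expression is None
            or np.array_equal(self.expression, other.expression)
        )
        return expr_eq and all(
            getattr(self, f) == getattr(other, f)
            for f in ("peak_id", "chrom", "start", "end", "strand", "summit",
                      "width80", "category", "assigned_gene")
        )


ACR_LABELS = ("Intergenic", "Intragenic", "TE", "Promoter")


@dataclass
class AcrPeak:
    peak_id: str
    chrom: str
    start: int
    end: int
    summit: int
    annotation: Optional[str] = None
    accessibility: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"ACR {self.peak_id}: summit outside interval")
        if self.annotation is not None and self.annotation not in ACR_LABELS:
            raise ValueError(f"ACR {self.peak_id}: bad label {self.annotation!r}")


@dataclass
class TranscriptCandidate:
    """A de-novo reconstructed transcript candidate (assembler output)."""

    tx_id: str
    chrom: str
    start: int
    end: int
    strand: str
    source: str = "assembler"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"transcript {self.tx_id}: start must be < end")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


class ExpressionMatrix:
    """Feature x sample matrix of non-negative expression values (CPM or TPM).

    ``mutant_samples`` marks the exosome-mutant columns; every statistic
    that is defined over the developmental time course masks them out.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        mutant_samples: Sequence[str] = (),
    ) -> None:
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise StructuralError(f"duplicated feature ids: {dupes}")
        if (values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        unknown = set(mutant_samples) - set(values.columns)
        if unknown:
            raise ValueError(f"mutant samples not in matrix: {sorted(unknown)}")
        self.values = values.astype(float)
        self.mutant_samples = list(mutant_samples)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def timecourse_samples(self) -> list[str]:
        return [s for s in self.values.columns if s not in self.mutant_samples]

    def row(self, feature_id: str, masked: bool = False) -> np.ndarray:
        cols = self.timecourse_samples if masked else self.samples
        return self.values.loc[feature_id, cols].to_numpy(dtype=float)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.values.index


class SignalTrack:
    """Per-chromosome, per-strand base-resolution signal.

    Backed by dense arrays (chromosomes here are at most a few Mbp); all
    values are non-negative, minus-strand values stored as magnitudes.
    """

    def __init__(self, chrom_lengths: Optional[dict[str, int]] = None) -> None:
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else None
        self._arr: dict[tuple[str, str], np.ndarray] = {}

    # -- construction -----------------------------------------------------

    def _array(self, chrom: str, strand: str, min_len: int = 0) -> np.ndarray:
        key = (chrom, strand)
        if key not in self._arr:
            if self.chrom_lengths is not None:
                if chrom not in self.chrom_lengths:
                    raise KeyError(f"unknown chromosome {chrom!r}")
                length = self.chrom_lengths[chrom]
                if min_len > length:
                    raise ValueError(
                        f"interval beyond declared length of {chrom} ({length})"
                    )
            else:
                length = max(min_len, 1)
            self._arr[key] = np.zeros(length)
        arr = self._arr[key]
        if min_len > arr.size:
            if self.chrom_lengths is not None:
                raise ValueError(
                    f"interval beyond declared length of {chrom} ({arr.size})"
                )
            warnings.warn(
                f"auto-extending {chrom}:{strand} track to {min_len} bp "
                "(no chromosome lengths declared)"
            )
            grown = np.zeros(min_len)
            grown[: arr.size] = arr
            self._arr[key] = grown
        return self._arr[key]

    def add(self, chrom: str, strand: str, start: int, end: int, value: float) -> None:
        arr = self._array(chrom, strand, min_len=end)
        arr[start:end] += value

    def add_at(self, chrom: str, strand: str, positions: np.ndarray,
               counts: Optional[np.ndarray] = None) -> None:
        if len(positions) == 0:
            return
        arr = self._array(chrom, strand, min_len=int(np.max(positions)) + 1)
        if counts is None:
            np.add.at(arr, positions, 1.0)
        else:
            np.add.at(arr, positions, counts)

    # -- queries ----------------------------------------------------------

    def chroms(self) -> list[str]:
        if self.chrom_lengths is not None:
            return list(self.chrom_lengths)
        return sorted({c for c, _ in self._arr})

    def window(self, chrom: str, strand: str, start: int, end: int
               ) -> tuple[np.ndarray, bool]:
        """Values over [start, end); out-of-bounds positions are zero-padded.

        Returns ``(values, padded)`` where ``padded`` flags any clipping.
        """
        if end <= start:
            return np.zeros(0), False
        key = (chrom, strand)
        arr = self._arr.get(key)
        if arr is None:
            length = (self.chrom_lengths or {}).get(chrom, end)
            out = np.zeros(end - start)
            return out, start < 0 or end > length
        out = np.zeros(end - start)
        lo, hi = max(start, 0), min(end, arr.size)
        if hi > lo:
            out[lo - start: hi - start] = arr[lo:hi]
        return out, start < 0 or end > arr.size

    def values(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        return self.window(chrom, strand, start, end)[0]

    def region_sum(self, chrom: str, strand: str, start: int, end: int) -> float:
        return float(self.values(chrom, strand, start, end).sum())

    def scaled(self, factor: float) -> "SignalTrack":
        out = SignalTrack(self.chrom_lengths)
        out._arr = {k: v * factor for k, v in self._arr.items()}
        return out

    @classmethod
    def pooled(cls, tracks: Iterable["SignalTrack"]) -> "SignalTrack":
        tracks = list(tracks)
        if not tracks:
            raise ValueError("no tracks to pool")
        out = cls(tracks[0].chrom_lengths)
        for t in tracks:
            for (chrom, strand), arr in t._arr.items():
                tgt = out._array(chrom, strand, min_len=arr.size)
                tgt[: arr.size] += arr
        return out


def oriented_window(anchor: int, strand: str, upstream: int, downstream: int
                    ) -> tuple[int, int]:
    """Half-open interval covering ``anchor`` from -upstream to +downstream
    in transcription orientation (both offsets inclusive of the base)."""
    if strand == "+":
        return anchor - upstream, anchor + downstream + 1
    return anchor - downstream, anchor + upstream + 1


# ---------------------------------------------------------------------------
# Analysis parameters
# ---------------------------------------------------------------------------


@dataclass
class AnalysisParameters:
    """Every tunable threshold of the pipeline (distances in bp).

    Defaults follow the published analysis this pipeline reproduces:
    TSS-to-gene assignment window (500 up / 200 down, first 25% of the
    transcript), antisense TTS extension 200 bp with the proximal rule
    (first 50% of the gene body and >1 kbp from the TTS), bidirectional
    pairing within 500 bp, enhancers resized to >=500 bp and linked to
    genes within 5 kbp at r >= 0.5, and the exosome-sensitivity gates.
    """

    assign_upstream: int = 500
    assign_downstream: int = 200
    assign_frac: float = 0.25
    antisense_tts_ext: int = 200
    proximal_frac: float = 0.5
    proximal_tts_min: int = 1000
    bidir_max_dist: int = 500
    width_frac: float = 0.8
    heatmap_trim_pct: float = 90.0
    min_tx_len: int = 200
    tx_tss_tol: int = 50
    enhancer_min_width: int = 500
    enhancer_gene_window: int = 5000
    target_corr_min: float = 0.5
    corr_group_bound: float = 0.25
    exo_lfc_sens: float = 2.0
    exo_q: float = 0.05
    exo_lfc_insens: float = 1.0
    exo_min_cpm: float = 1.0
    exo_min_tpm: float = 0.1
    const_min_cpm: float = 50.0
    const_top_n: int = 500
    acr_promoter_up: int = 400
    acr_promoter_down: int = 100
    rank_n: int = 500

    def __post_init__(self) -> None:
        for name in ("assign_upstream", "assign_downstream", "antisense_tts_ext",
                     "proximal_tts_min", "bidir_max_dist", "min_tx_len",
                     "tx_tss_tol", "enhancer_min_width", "enhancer_gene_window",
                     "acr_promoter_up", "acr_promoter_down"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive distance")
        for name in ("assign_frac", "proximal_frac", "width_frac"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GENE_TYPES = {"gene", "pseudogene", "transposable_element_gene"}
_UTR5_TYPES = {"five_prime_UTR", "5UTR"}


def _validate_gff3_lines(path: str) -> int:
    """Pre-pass: column/coordinate validation with line numbers. Returns the
    number of feature lines."""
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer start/end "
                    f"({cols[3]!r}, {cols[4]!r})"
                ) from None
            if start < 1 or end < start:
                raise ParseError(
                    f"{path}: line {lineno}: bad 1-based interval [{start},{end}]"
                )
            if cols[6] not in ("+", "-", ".", "?"):
                raise ParseError(f"{path}: line {lineno}: bad strand {cols[6]!r}")
            n += 1
    return n


def read_gff3(path: str) -> GenomeAnnotation:
    """Read a GFF3 gene annotation into internal 0-based half-open models.

    Chromosome lengths come from ``##sequence-region`` pragmas when present,
    otherwise from the furthest feature end per chromosome.  Gene biotype is
    taken from a ``biotype``/``gene_biotype``/``locus_type`` attribute when
    present and preserved verbatim (unknown biotypes allowed); genes without
    one default to ``protein_coding``.  A gene with no child transcripts gets
    a single synthesized transcript spanning the gene body.
    """
    import gffutils

    n_features = _validate_gff3_lines(path)

    chrom_from_pragma: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    # pragma is 1-based inclusive: length = end
                    chrom_from_pragma[parts[1]] = int(parts[3])

    if n_features == 0:
        return GenomeAnnotation(
            chromosomes=sorted(chrom_from_pragma.items()), genes=[]
        )

    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        checklines=0,
    )

    gene_features = []
    for gtype in sorted(_GENE_TYPES):
        gene_features.extend(db.features_of_type(gtype))
    gene_ids = {f.id for f in gene_features}

    # structural check: any second-level feature must point at a known gene
    for f in db.all_features():
        if f.featuretype in _GENE_TYPES:
            continue
        parents = f.attributes.get("Parent", [])
        for p in parents:
            if p not in gene_ids and p not in {x.id for x in db.all_features()}:
                raise StructuralError(
                    f"{path}: feature {f.id!r} has unknown parent {p!r}"
                )

    genes: list[GeneModel] = []
    max_end: dict[str, int] = {}
    for f in sorted(gene_features, key=lambda x: (x.seqid, x.start, x.id)):
        biotype = None
        for key in ("biotype", "gene_biotype", "locus_type"):
            if key in f.attributes:
                biotype = f.attributes[key][0]
                break
        if f.featuretype == "transposable_element_gene":
            biotype = biotype or "transposable_element_gene"
        if f.featuretype == "pseudogene":
            biotype = biotype or "pseudogene"
        biotype = biotype or "protein_coding"

        transcripts: list[TranscriptModel] = []
        for child in db.children(f, level=1):
            if child.featuretype in _UTR5_TYPES:
                continue
            utr_end = None
            utrs = [u for u in db.children(child, level=1)
                    if u.featuretype in _UTR5_TYPES]
            if utrs:
                if f.strand == "+":
                    utr_end = max(u.end for u in utrs)  # 1-based closed == 0-based open
                else:
                    utr_end = min(u.start - 1 for u in utrs)
            transcripts.append(
                TranscriptModel(
                    tx_id=child.id, start=child.start - 1, end=child.end,
                    five_prime_utr_end=utr_end,
                )
            )
        if not transcripts:
            transcripts = [TranscriptModel(f"{f.id}.1", f.start - 1, f.end)]

        genes.append(
            GeneModel(
                gene_id=f.id,
                chrom=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand if f.strand in ("+", "-") else "+",
                biotype=biotype,
                transcripts=transcripts,
            )
        )
        max_end[f.seqid] = max(max_end.get(f.seqid, 0), f.end)

    chrom_lengths = dict(max_end)
    chrom_lengths.update(chrom_from_pragma)
    return GenomeAnnotation(
        chromosomes=sorted(chrom_lengths.items()), genes=genes
    )


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def _read_bedgraph_into(track: SignalTrack, path: str, strand: str,
                        allow_negative: bool) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if (not line or line.startswith(("#", "track", "browser"))):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected 4 columns, got {len(cols)}"
                )
            chrom = cols[0]
            try:
                start, end, value = int(cols[1]), int(cols[2]), float(cols[3])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric coordinates/value"
                ) from None
            if end <= start or start < 0:
                raise ParseError(f"{path}: line {lineno}: bad interval")
            if value < 0:
                if not allow_negative:
                    raise ParseError(
                        f"{path}: line {lineno}: negative value on plus-strand file"
                    )
                value = abs(value)
            track.add(chrom, strand, start, end, value)


def read_bedgraph_pair(
    plus_path: str,
    minus_path: str,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> SignalTrack:
    """Read a per-strand pair of bedGraph files into one SignalTrack.

    Overlapping intervals within a file are summed.  Minus-strand values may
    be written negated (a common track convention) and are stored as
    magnitudes.
    """
    track = SignalTrack(chrom_lengths)
    _read_bedgraph_into(track, plus_path, "+", allow_negative=False)
    _read_bedgraph_into(track, minus_path, "-", allow_negative=True)
    return track


def write_bedgraph_pair(track: SignalTrack, plus_path: str, minus_path: str,
                        decimals: int = 6) -> None:
    """Write one bedGraph per strand, run-length-encoding equal values."""
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        with open(path, "w") as fh:
            for chrom in track.chroms():
                arr = track._arr.get((chrom, strand))
                if arr is None or not arr.any():
                    continue
                rounded = np.round(arr, decimals)
                change = np.flatnonzero(np.diff(rounded)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [rounded.size]))
                for s, e in zip(starts, ends):
                    v = rounded[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.{decimals}g}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

_TSS_BED_EXTRA = ("summit", "width80", "category", "assigned_gene")
_ACR_BED_EXTRA = ("summit", "annotation")


def write_bed(features: Sequence, path: str) -> None:
    """Write features as BED6 (+ extra columns for TssPeak / AcrPeak).

    Expression/accessibility vectors are not serialized here; they live in
    the expression matrix keyed by feature id.
    """
    seen: set[str] = set()
    with open(path, "w") as fh:
        for f in features:
            name = (getattr(f, "peak_id", None) or getattr(f, "tx_id", None)
                    or getattr(f, "name"))
            if name in seen:
                raise StructuralError(f"duplicated feature id {name!r}")
            seen.add(name)
            strand = getattr(f, "strand", ".")
            row = [f.chrom, str(f.start), str(f.end), name, "0", strand]
            if isinstance(f, TssPeak):
                row += [
                    "." if f.summit is None else str(f.summit),
                    "." if f.width80 is None else str(f.width80),
                    f.category,
                    f.assigned_gene or ".",
                ]
            elif isinstance(f, AcrPeak):
                row += [str(f.summit), f.annotation or "."]
            fh.write("\t".join(row) + "\n")


@dataclass
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str
    score: float
    strand: str


def read_bed(path: str, kind: str = "auto"):
    """Read a BED file written by :func:`write_bed` (or any BED3+).

    ``kind`` may be ``"tss"``, ``"acr"``, ``"interval"`` or ``"auto"``
    (detected from the column count).  A missing score column defaults to 0,
    a missing strand to ``"+"``.
    """
    out = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            name = cols[3] if len(cols) > 3 else f"feature_{lineno}"
            if name in seen:
                raise StructuralError(f"{path}: duplicated feature id {name!r}")
            seen.add(name)
            score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0.0
            strand = cols[5] if len(cols) > 5 else "+"

            this_kind = kind
            if kind == "auto":
                this_kind = {10: "tss", 8: "acr"}.get(len(cols), "interval")
            if this_kind == "tss":
                summit = None if cols[6] == "." else int(cols[6])
                w80 = None if cols[7] == "." else int(cols[7])
                out.append(
                    TssPeak(
                        peak_id=name, chrom=chrom, start=start, end=end,
                        strand=strand, summit=summit, width80=w80,
                        category=cols[8],
                        assigned_gene=None if cols[9] == "." else cols[9],
                    )
                )
            elif this_kind == "acr":
                out.append(
                    AcrPeak(
                        peak_id=name, chrom=chrom, start=start, end=end,
                        summit=int(cols[6]),
                        annotation=None if cols[7] == "." else cols[7],
                    )
                )
            else:
                out.append(BedInterval(chrom, start, end, name, score, strand))
    return out


# ---------------------------------------------------------------------------
# TSV matrices and differential-expression tables
# ---------------------------------------------------------------------------


def write_matrix(matrix: ExpressionMatrix, path: str, decimals: int = 6) -> None:
    df = matrix.values.round(decimals)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format=f"%.{decimals}g")


def read_matrix(path: str, mutant_samples: Sequence[str] = ()) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise StructuralError(f"{path}: duplicated feature ids: {dupes}")
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-numeric value at feature {row!r}, sample {col!r}"
            )
        values[col] = converted
    return ExpressionMatrix(values, mutant_samples=mutant_samples)


DE_COLUMNS = ("feature_id", "log2FC", "qvalue")


def write_de_table(df: pd.DataFrame, path: str) -> None:
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table missing columns {missing}")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_de_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: DE table missing columns {missing}")
    if df["feature_id"].duplicated().any():
        raise StructuralError(f"{path}: duplicated feature ids in DE table")
    for col in df.columns:
        if col == "feature_id":
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            i = int(bad.to_numpy().nonzero()[0][0])
            raise ParseError(
                f"{path}: non-numeric value in column {col!r}, "
                f"row {df['feature_id'].iloc[i]!r}"
            )
        df[col] = converted
    return df
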