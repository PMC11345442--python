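"""Domain containers and file I/O.

Every interval in the package is 0-based half-open (BED convention).
Inputs in 1-based closed coordinates (GFF-style) must be converted at the
boundary with :func:`from_one_based_closed`. Strand is ignored throughout:
circular-DNA intervals and GC content are strand-symmetric quantities.

Readers cover the external representations the pipeline touches:

* genome FASTA (via Biopython),
* eccDNA interval catalogs in a Circle-Map-style circular BED dialect
  (``chrom  start  end  discordant  split  score``) or plain BED3,
* gene / repeat annotation BED (column 4 = gene id or RepeatMasker class),
* tabular copy-number segments, expression matrices and survival tables.

All report writers emit TSV with a ``#`` metadata preamble recording the
package version, seed and parameters, so every number in a report is
reproducible from its header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeModel",
    "EccDNARecord",
    "EccDNACatalog",
    "AnnotationTrack",
    "CNSegmentSet",
    "ExpressionMatrix",
    "SurvivalCohort",
    "FormatError",
    "from_one_based_closed",
    "read_genome_fasta",
    "write_genome_fasta",
    "read_eccdna_catalog",
    "write_eccdna_catalog",
    "read_annotation",
    "write_annotation",
    "read_cn_segments",
    "write_cn_segments",
    "read_expression",
    "write_expression",
    "read_survival",
    "write_survival",
    "write_report",
    "read_report",
    "REGION_CLASSES",
    "REPEAT_CLASSES",
    "FEATURE_CLASSES",
]

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised on malformed input files; the message names the offending line."""


#: genomic-region classes used by the exclusive region partition
REGION_CLASSES = ("gene", "exon", "CDS", "UTR5", "UTR3", "intron", "intergenic")

#: repeat-element classes (RepeatMasker family level, Alu split from other SINEs)
REPEAT_CLASSES = (
    "SINE",
    "Alu",
    "LINE",
    "LTR",
    "simple_repeat",
    "low_complexity",
    "DNA_transposon",
    "satellite",
    "other_repeat",
)

#: the closed feature-class vocabulary of annotation tracks
FEATURE_CLASSES = REGION_CLASSES + REPEAT_CLASSES

# RepeatMasker class/family strings -> closed vocabulary. Matching is on the
# class component before '/', except Alu which is detected from the family.
_REPEAT_CLASS_MAP = {
    "sine": "SINE",
    "line": "LINE",
    "ltr": "LTR",
    "simple_repeat": "simple_repeat",
    "low_complexity": "low_complexity",
    "dna": "DNA_transposon",
    "dna_transposon": "DNA_transposon",
    "satellite": "satellite",
}


def normalize_repeat_label(label: str) -> str:
    """Map a RepeatMasker-style class string onto the closed vocabulary.

    ``SINE/Alu`` (and anything whose family component contains ``Alu``)
    maps to ``Alu``; unknown labels map to ``other_repeat`` with a logged
    warning.
    """
    raw = label.strip()
    if raw in REPEAT_CLASSES:
        return raw
    head, _, family = raw.partition("/")
    if "alu" in family.lower() or head.lower() == "alu":
        return "Alu"
    mapped = _REPEAT_CLASS_MAP.get(head.lower())
    if mapped is None:
        log.warning("unknown repeat class %r mapped to other_repeat", raw)
        return "other_repeat"
    return mapped


def from_one_based_closed(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based closed interval to 0-based half-open.

    The converted interval covers exactly the same bases, so no interval
    shrinks and pairwise overlaps are preserved.
    """
    if start < 1 or end < start:
        raise ValueError(f"invalid 1-based closed interval ({start}, {end})")
    return start - 1, end


# ---------------------------------------------------------------------------
# genome


@dataclass(eq=False)
class GenomeModel:
    """An in-memory genome: ordered chromosome names and uppercase sequences."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError("genome has no chromosomes")
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"chromosome {name!r} has empty sequence")
        self._codes: dict[str, np.ndarray] = {}

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def codes(self, chrom: str) -> np.ndarray:
        """Byte codes of a chromosome (cached), for vectorised base counting."""
        arr = self._codes.get(chrom)
        if arr is None:
            arr = np.frombuffer(self.sequences[chrom].encode("ascii"), dtype=np.uint8)
            self._codes[chrom] = arr
        return arr

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= start <= end <= len(self.sequences[chrom])):
            raise ValueError(f"interval [{start}, {end}) outside {chrom}")
        return self.sequences[chrom][start:end]


def read_genome_fasta(path: str | Path) -> GenomeModel:
    """Read a FASTA genome; sequences are uppercased, N is allowed."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty FASTA record {rec.id!r}")
        sequences[rec.id] = seq
    if not sequences:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeModel(sequences)


def write_genome_fasta(genome: GenomeModel, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# eccDNA catalogs


class EccDNARecord(NamedTuple):
    """One circular-DNA call: 0-based half-open interval with read support."""

    chrom: str
    start: int
    end: int
    split_reads: int = 0
    discordant_reads: int = 0
    score: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start


_CATALOG_COLUMNS = ["chrom", "start", "end", "split_reads", "discordant_reads", "score"]


@dataclass
class EccDNACatalog:
    """A per-sample collection of eccDNA records.

    ``records`` is a DataFrame with columns chrom/start/end/split_reads/
    discordant_reads/score, sorted by (chrom, start, end).
    ``mapped_read_total`` is the normalization denominator for EPM
    (eccDNAs per million mapped reads); ``group_label`` the optional H/L
    stratum.
    """

    sample_id: str
    records: pd.DataFrame
    mapped_read_total: int | None = None
    group_label: str | None = None

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=_CATALOG_COLUMNS).copy()
        for col, dtype in (
            ("start", np.int64),
            ("end", np.int64),
            ("split_reads", np.int64),
            ("discordant_reads", np.int64),
            ("score", float),
        ):
            df[col] = df[col].fillna(0).astype(dtype)
        df["chrom"] = df["chrom"].astype(str)
        bad = df["start"] >= df["end"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"zero-length interval in catalog {self.sample_id!r}, row {i}")
        if (df["start"] < 0).any():
            raise FormatError(f"negative coordinate in catalog {self.sample_id!r}")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.records = df
        if self.mapped_read_total is not None and self.mapped_read_total <= 0:
            raise ValueError("mapped_read_total must be positive")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EccDNARecord]:
        for row in self.records.itertuples(index=False):
            yield EccDNARecord(
                row.chrom, int(row.start), int(row.end),
                int(row.split_reads), int(row.discordant_reads), float(row.score),
            )

    @property
    def lengths(self) -> np.ndarray:
        return (self.records["end"] - self.records["start"]).to_numpy()

    def validate_against(self, genome: GenomeModel) -> pd.DataFrame:
        """Return records lying on genome chromosomes within bounds.

        Records on unknown chromosomes are retained in the catalog (and in
        abundance counts) but excluded from sequence-dependent analyses;
        the exclusion tally is logged.
        """
        lens = self.records["chrom"].map(genome.lengths)
        ok = lens.notna() & (self.records["end"] <= lens.fillna(0))
        n_bad = int((~ok).sum())
        if n_bad:
            log.warning(
                "catalog %s: %d records off the genome excluded from sequence analyses",
                self.sample_id, n_bad,
            )
        return self.records[ok]


def read_eccdna_catalog(
    path: str | Path,
    dialect: str = "circlemap_bed",
    mapped_read_total: int | None = None,
    sample_id: str | None = None,
    min_split: int = 0,
) -> EccDNACatalog:
    """Read an eccDNA catalog from a BED-dialect file.

    ``circlemap_bed`` expects >= 6 tab-separated columns in the order
    (chrom, start, end, discordant, split, score); ``plain_bed`` expects
    >= 3 and defaults read support to zero. Extra columns are ignored.
    ``min_split`` optionally filters calls by split-read support; by
    default every row is accepted.
    """
    if dialect not in ("circlemap_bed", "plain_bed"):
        raise ValueError(f"unknown catalog dialect {dialect!r}")
    min_cols = 6 if dialect == "circlemap_bed" else 3
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_cols:
                raise FormatError(f"{path}: expected >= {min_cols} columns, line {lineno}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}: malformed coordinate, line {lineno}") from exc
            if start >= end:
                raise FormatError(f"{path}: zero-length interval, line {lineno}")
            if dialect == "circlemap_bed":
                try:
                    discordant = int(float(parts[3]))
                    split = int(float(parts[4]))
                    score = float(parts[5])
                except ValueError as exc:
                    raise FormatError(f"{path}: malformed read support, line {lineno}") from exc
            else:
                discordant = split = 0
                score = 0.0
            rows.append((chrom, start, end, split, discordant, score))
    df = pd.DataFrame(rows, columns=_CATALOG_COLUMNS)
    if min_split > 0:
        df = df[df["split_reads"] >= min_split]
    sid = sample_id if sample_id is not None else Path(path).stem
    return EccDNACatalog(sid, df, mapped_read_total=mapped_read_total)


def write_eccdna_catalog(catalog: EccDNACatalog, path: str | Path) -> None:
    """Write a catalog in the Circle-Map circular-BED column order."""
    out = catalog.records[["chrom", "start", "end", "discordant_reads", "split_reads", "score"]]
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# annotation tracks


@dataclass
class AnnotationTrack:
    """Labeled genomic intervals (genes, gene parts, or repeat elements).

    ``features`` columns: chrom, start, end, feature_class, gene_id
    (gene_id is empty for repeat features).
    """

    features: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(
            self.features, columns=["chrom", "start", "end", "feature_class", "gene_id"]
        ).copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["chrom"] = df["chrom"].astype(str)
        df["gene_id"] = df["gene_id"].fillna("").astype(str)
        if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
            raise FormatError("annotation contains a degenerate interval")
        unknown = set(df["feature_class"]) - set(FEATURE_CLASSES)
        if unknown:
            raise FormatError(f"feature classes outside the vocabulary: {sorted(unknown)}")
        missing_gene = (df["feature_class"] == "gene") & (df["gene_id"] == "")
        if missing_gene.any():
            raise FormatError("gene features must carry a gene_id")
        self.features = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.features)

    def subset(self, classes: Iterable[str]) -> pd.DataFrame:
        return self.features[self.features["feature_class"].isin(set(classes))]

    def validate_against(self, genome: GenomeModel) -> None:
        lens = self.features["chrom"].map(genome.lengths)
        if lens.isna().any() or (self.features["end"] > lens).any():
            raise FormatError("annotation features extend beyond the genome")


def read_annotation(path: str | Path, kind: str) -> AnnotationTrack:
    """Read a BED-like annotation file.

    ``gene_bed``: column 4 is the gene id; the feature class is ``gene``
    unless column 5 names a class from the region vocabulary (allowing
    exon/intron/UTR sub-features to share the file).
    ``repeat_bed``: column 4 is a RepeatMasker-style class string,
    normalized onto the closed vocabulary.
    """
    if kind not in ("gene_bed", "repeat_bed"):
        raise ValueError(f"unknown annotation kind {kind!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: missing class/id column, line {lineno}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}: malformed coordinate, line {lineno}") from exc
            if kind == "repeat_bed":
                rows.append((chrom, start, end, normalize_repeat_label(parts[3]), ""))
            else:
                cls = "gene"
                if len(parts) >= 5 and parts[4] in REGION_CLASSES:
                    cls = parts[4]
                rows.append((chrom, start, end, cls, parts[3]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "feature_class", "gene_id"])
    return AnnotationTrack(df)


def write_annotation(track: AnnotationTrack, path: str | Path, kind: str) -> None:
    with open(path, "w") as fh:
        for row in track.features.itertuples(index=False):
            if kind == "repeat_bed":
                col4 = row.feature_class
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{col4}\n")
            else:
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t{row.feature_class}\n"
                )


# ---------------------------------------------------------------------------
# copy-number segments


@dataclass
class CNSegmentSet:
    """Per-sample integer copy-number segments tiling every chromosome.

    ``segments`` columns: chrom, start, end, cn. Per chromosome the
    segments must be non-overlapping and, when validated against declared
    chromosome lengths, gap-free (a coverage gap is an error, not silence).
    """

    sample_id: str
    segments: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.segments, columns=["chrom", "start", "end", "cn"]).copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["cn"] = df["cn"].astype(np.int64)
        df["chrom"] = df["chrom"].astype(str)
        if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
            raise FormatError(f"degenerate CN segment in sample {self.sample_id!r}")
        if (df["cn"] < 0).any():
            raise FormatError(f"negative copy number in sample {self.sample_id!r}")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for chrom, grp in df.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise FormatError(f"overlapping CN segments on {chrom} in {self.sample_id!r}")
        self.segments = df

    def chromosome_lengths(self) -> dict[str, int]:
        return self.segments.groupby("chrom", sort=False)["end"].max().to_dict()

    def validate_tiling(self, lengths: dict[str, int] | None = None) -> None:
        lengths = lengths or self.chromosome_lengths()
        for chrom, grp in self.segments.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if starts[0] != 0 or (starts[1:] != ends[:-1]).any() or ends[-1] != lengths[chrom]:
                raise FormatError(
                    f"CN segments do not tile chromosome {chrom} in sample {self.sample_id!r}"
                )


def read_cn_segments(path: str | Path) -> list[CNSegmentSet]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "chrom", "start", "end", "cn"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: CN table must have columns {sorted(required)}")
    return [
        CNSegmentSet(str(sample), grp[["chrom", "start", "end", "cn"]])
        for sample, grp in df.groupby("sample", sort=False)
    ]


def write_cn_segments(segment_sets: Iterable[CNSegmentSet], path: str | Path) -> None:
    frames = []
    for ss in segment_sets:
        out = ss.segments.copy()
        out.insert(0, "sample", ss.sample_id)
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression and survival


@dataclass
class ExpressionMatrix:
    """Nonnegative normalized expression, genes (rows) x samples (columns)."""

    values: pd.DataFrame
    groups: pd.Series | None = None  # sample id -> group label, optional

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.values).copy()
        if df.index.duplicated().any():
            raise FormatError("duplicate gene ids in expression matrix")
        if (df.to_numpy() < 0).any():
            raise FormatError("expression values must be nonnegative")
        self.values = df
        if self.groups is not None:
            self.groups = pd.Series(self.groups)
            missing = set(df.columns) - set(self.groups.index)
            if missing:
                raise FormatError(f"samples without a group label: {sorted(missing)[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


@dataclass
class SurvivalCohort:
    """Patient survival table: id, time (days, > 0), event (1/0), score."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table).copy()
        required = {"patient", "time", "event"}
        if not required.issubset(df.columns):
            raise FormatError(f"survival table must have columns {sorted(required)}")
        if (df["time"] <= 0).any():
            raise FormatError("survival times must be positive")
        if not df["event"].isin([0, 1]).all():
            raise FormatError("event indicator must be 0 or 1")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def time(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    @property
    def score(self) -> np.ndarray:
        if "score" not in self.table.columns:
            raise KeyError("cohort carries no score column")
        return self.table["score"].to_numpy(dtype=float)


def read_survival(path: str | Path) -> SurvivalCohort:
    return SurvivalCohort(pd.read_csv(path, sep="\t", comment="#"))


def write_survival(cohort: SurvivalCohort, path: str | Path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# report TSVs with metadata preamble


def write_report(df: pd.DataFrame, path: str | Path, params: dict | None = None,
                 index: bool = False) -> None:
    """Write a report TSV with a ``#`` preamble of version, seed and parameters."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# eccdna-charter version={__version__}\n")
        for key, value in (params or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
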