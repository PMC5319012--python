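"""Readers for junction-count files, coverage tracks and project metadata.

Two junction dialects are supported:

* ``star_sj`` — STAR's ``SJ.out.tab``: chrom, intron first base (1-based),
  intron last base (1-based), strand code (0 undefined / 1 ``+`` / 2
  ``-``), motif, annotated flag, unique-mapping reads, multi-mapping
  reads, max overhang.  The unique-mapping read column is the count.
* ``minimal_tsv`` — four columns, already 0-based:
  chrom, donor_end, acceptor_start, count.

Coverage comes from bigwig (via pyBigWig) or bedgraph (plain text);
both densify to one float per base over the gene span, with missing data
as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .gene_model import GeneModel


class TrackError(ValueError):
    """Raised for malformed track or project input."""


@dataclass(frozen=True)
class Junction:
    """A splice junction identified by its intron [donor_end, acceptor_start).

    ``strand`` and ``known`` are annotations, not identity: two junction
    records with the same intron compare equal.
    """

    chrom: str
    donor_end: int
    acceptor_start: int
    strand: str = field(default=".", compare=False)
    known: bool = field(default=False, compare=False)

    def __post_init__(self):
        if self.donor_end >= self.acceptor_start:
            raise TrackError(
                f"junction donor_end must precede acceptor_start, got "
                f"({self.donor_end}, {self.acceptor_start})"
            )

    @property
    def intron(self) -> tuple[int, int]:
        return self.donor_end, self.acceptor_start


class JunctionTable:
    """Merged per-sample junction counts with an interval index.

    One row per unique junction across all samples; ``counts`` is a
    junction x sample matrix of raw read counts (absent entries are 0).
    """

    def __init__(self, junctions: Sequence[Junction], counts: np.ndarray,
                 samples: Sequence[str]):
        self.junctions = list(junctions)
        self.counts = np.asarray(counts, dtype=float)
        self.samples = list(samples)
        if self.counts.shape != (len(self.junctions), len(self.samples)):
            raise TrackError("counts shape does not match junctions x samples")
        if (self.counts < 0).any():
            raise TrackError("negative junction counts")
        self._trees: dict[str, IntervalTree] = {}
        for i, j in enumerate(self.junctions):
            self._trees.setdefault(j.chrom, IntervalTree())[
                j.donor_end:j.acceptor_start
            ] = i

    def __len__(self) -> int:
        return len(self.junctions)

    def row(self, junction: Junction) -> np.ndarray:
        i = self.junctions.index(junction)
        return self.counts[i]

    def query(self, chrom: str, start: int, end: int) -> list[int]:
        """Row indices of junctions whose intron is fully inside [start, end)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.envelop(start, end))
        return hits

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "chrom": [j.chrom for j in self.junctions],
                "donor_end": [j.donor_end for j in self.junctions],
                "acceptor_start": [j.acceptor_start for j in self.junctions],
                "strand": [j.strand for j in self.junctions],
                "known": [j.known for j in self.junctions],
            }
        )
        counts = pd.DataFrame(self.counts, columns=self.samples)
        return pd.concat([meta, counts], axis=1)


@dataclass
class CoverageSet:
    """Dense per-sample per-base coverage over one gene span."""

    chrom: str
    start: int
    end: int
    samples: list[str]
    conditions: list[str]
    matrix: np.ndarray  # samples x span-length, raw
    size_factors: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.samples), self.end - self.start):
            raise TrackError("coverage matrix shape mismatch")
        if (self.matrix < 0).any():
            raise TrackError("negative coverage")

    def adjusted(self) -> np.ndarray:
        """Coverage divided by per-sample size factors (1.0 if unset)."""
        if self.size_factors is None:
            return self.matrix
        return self.matrix / np.asarray(self.size_factors)[:, None]

    def condition_samples(self, condition: str) -> list[int]:
        return [i for i, c in enumerate(self.conditions) if c == condition]

    def condition_mean(self, condition: str) -> np.ndarray:
        """Mean adjusted coverage per base across the condition's samples."""
        rows = self.condition_samples(condition)
        if not rows:
            raise TrackError(f"no samples for condition {condition!r}")
        return self.adjusted()[rows].mean(axis=0)


@dataclass
class ProjectConfig:
    """Sample sheet: ids, condition labels, file paths, optional factors."""

    samples: list[str]
    conditions: dict[str, str]
    bigwig_paths: dict[str, Path]
    junction_paths: dict[str, Path]
    size_factors: dict[str, float] | None = None

    def __post_init__(self):
        if len(set(self.samples)) != len(self.samples):
            raise TrackError("duplicate sample ids in project")

    @property
    def condition_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            c = self.conditions[s]
            if c not in seen:
                seen.append(c)
        return seen

    def require_testable(self) -> None:
        """Detection needs >=2 conditions, each with >=2 samples."""
        counts: dict[str, int] = {}
        for s in self.samples:
            counts[self.conditions[s]] = counts.get(self.conditions[s], 0) + 1
        if len(counts) < 2 or any(n < 2 for n in counts.values()):
            raise TrackError(
                "detection requires >=2 conditions with >=2 samples each; "
                f"got {counts}"
            )


PROJECT_COLUMNS = ["sample", "condition", "bigwig", "junctions"]


def read_project(path: str | Path) -> ProjectConfig:
    """Read the tab-separated project file (header: sample, condition,
    bigwig, junctions, optional size_factor).  Relative paths resolve
    against the project file's directory."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PROJECT_COLUMNS if c not in df.columns]
    if missing:
        raise TrackError(f"{path}: project file missing columns {missing}")
    base = path.parent
    samples = df["sample"].tolist()
    conditions = dict(zip(samples, df["condition"]))
    bw = {s: base / p for s, p in zip(samples, df["bigwig"])}
    jc = {s: base / p for s, p in zip(samples, df["junctions"])}
    factors = None
    if "size_factor" in df.columns and df["size_factor"].notna().all():
        factors = {s: float(f) for s, f in zip(samples, df["size_factor"])}
        if any(f <= 0 for f in factors.values()):
            raise TrackError(f"{path}: size factors must be positive")
    return ProjectConfig(samples, conditions, bw, jc, factors)


def write_project(config: ProjectConfig, path: str | Path) -> None:
    rows = []
    for s in config.samples:
        row = {
            "sample": s,
            "condition": config.conditions[s],
            "bigwig": str(config.bigwig_paths[s]),
            "junctions": str(config.junction_paths[s]),
        }
        if config.size_factors is not None:
            row["size_factor"] = config.size_factors[s]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Junction I/O


def read_junction_file(
    path: str | Path, dialect: str = "minimal_tsv"
) -> list[tuple[Junction, int]]:
    """Read one sample's junction counts.

    STAR rows convert their 1-based intron first/last base to the internal
    0-based half-open convention: intron 1001..2000 (1-based inclusive)
    becomes [1000, 2000), i.e. donor_end=1000, acceptor_start=2000.
    """
    path = Path(path)
    out: list[tuple[Junction, int]] = []
    strand_codes = {"0": ".", "1": "+", "2": "-"}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "star_sj":
                if len(fields) < 9:
                    raise TrackError(
                        f"{path}:{lineno}: STAR SJ rows need 9 columns"
                    )
                chrom = fields[0]
                donor_end = int(fields[1]) - 1
                acceptor_start = int(fields[2])
                strand = strand_codes.get(fields[3], ".")
                count = int(fields[6])
            elif dialect == "minimal_tsv":
                if len(fields) < 4:
                    raise TrackError(
                        f"{path}:{lineno}: minimal junction rows need 4 columns"
                    )
                chrom = fields[0]
                donor_end = int(fields[1])
                acceptor_start = int(fields[2])
                strand = "."
                count = int(fields[3])
            else:
                raise TrackError(f"unknown junction dialect {dialect!r}")
            if count < 0:
                raise TrackError(f"{path}:{lineno}: negative count {count}")
            out.append(
                (Junction(chrom, donor_end, acceptor_start, strand), count)
            )
    return out


def write_junction_file(
    entries: Iterable[tuple[Junction, int]],
    path: str | Path,
    dialect: str = "minimal_tsv",
) -> None:
    lines = []
    strand_codes = {".": "0", "+": "1", "-": "2"}
    for j, count in entries:
        if dialect == "minimal_tsv":
            lines.append(f"{j.chrom}\t{j.donor_end}\t{j.acceptor_start}\t{count}")
        elif dialect == "star_sj":
            lines.append(
                "\t".join(
                    [j.chrom, str(j.donor_end + 1), str(j.acceptor_start),
                     strand_codes.get(j.strand, "0"), "0", "1",
                     str(count), "0", "50"]
                )
            )
        else:
            raise TrackError(f"unknown junction dialect {dialect!r}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def merge_junction_tables(
    per_sample: Sequence[tuple[str, Sequence[tuple[Junction, int]]]],
    annotation: Iterable[GeneModel] | None = None,
) -> JunctionTable:
    """Union-merge per-sample junction lists into one indexed table.

    Column order follows the input sample order; junctions with zero
    counts in every sample are dropped.  When an annotation is given,
    each junction is flagged ``known`` by membership among annotated
    introns, and an undefined strand is inferred from the matching
    annotated gene.
    """
    if not per_sample:
        raise TrackError("need at least one sample")
    samples = [s for s, _ in per_sample]
    keyed: dict[tuple[str, int, int], np.ndarray] = {}
    strands: dict[tuple[str, int, int], str] = {}
    for col, (_, entries) in enumerate(per_sample):
        for j, count in entries:
            key = (j.chrom, j.donor_end, j.acceptor_start)
            if key not in keyed:
                keyed[key] = np.zeros(len(samples))
                strands[key] = j.strand
            keyed[key][col] += count
            if strands[key] == ".":
                strands[key] = j.strand
    known_introns: dict[tuple[str, int, int], str] = {}
    gene_spans: list[tuple[str, int, int, str]] = []
    if annotation is not None:
        for gene in annotation:
            for intron in gene.introns:
                known_introns[(gene.chrom, *intron)] = gene.strand
            gene_spans.append((gene.chrom, *gene.span, gene.strand))
    junctions: list[Junction] = []
    rows: list[np.ndarray] = []
    for key in sorted(keyed):
        counts = keyed[key]
        if counts.sum() == 0:
            continue
        strand = strands[key]
        known = key in known_introns
        if known:
            strand = known_introns[key]
        elif strand == ".":
            # infer from the gene whose span contains the intron
            containing = [
                gs for gs in gene_spans
                if gs[0] == key[0] and gs[1] <= key[1] and key[2] <= gs[2]
            ]
            if len(containing) == 1:
                strand = containing[0][3]
        junctions.append(Junction(*key, strand=strand, known=known))
        rows.append(counts)
    counts = np.vstack(rows) if rows else np.zeros((0, len(samples)))
    return JunctionTable(junctions, counts, samples)


def query_junctions(
    table: JunctionTable, chrom: str, start: int, end: int
) -> list[tuple[Junction, np.ndarray]]:
    """Junctions (with count rows) whose intron lies fully inside the range."""
    return [(table.junctions[i], table.counts[i])
            for i in table.query(chrom, start, end)]


# ---------------------------------------------------------------------------
# Coverage I/O


def _read_bedgraph(path: Path, chrom: str, start: int, end: int) -> np.ndarray:
    arr = np.zeros(end - start)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise TrackError(f"{path}:{lineno}: bedgraph rows need 4 columns")
            if fields[0] != chrom:
                continue
            s, e, v = int(fields[1]), int(fields[2]), float(fields[3])
            s, e = max(s, start), min(e, end)
            if s < e:
                arr[s - start:e - start] = v
    return arr


def _read_bigwig(path: Path, chrom: str, start: int, end: int) -> np.ndarray:
    import pyBigWig

    bw = pyBigWig.open(str(path))
    try:
        if chrom not in bw.chroms():
            return np.zeros(end - start)
        chrom_len = bw.chroms()[chrom]
        hi = min(end, chrom_len)
        arr = np.zeros(end - start)
        if start < hi:
            vals = np.asarray(bw.values(chrom, start, hi, numpy=True), dtype=float)
            vals[np.isnan(vals)] = 0.0
            arr[: hi - start] = vals
        return arr
    finally:
        bw.close()


def read_coverage(
    project: ProjectConfig, chrom: str, start: int, end: int
) -> CoverageSet:
    """Load dense per-base coverage over a gene span for every sample.

    File format is chosen by extension: ``.bw``/``.bigwig`` via pyBigWig,
    anything else parsed as bedgraph.  Bases without data are 0.
    """
    rows = []
    for s in project.samples:
        path = Path(project.bigwig_paths[s])
        try:
            if path.suffix.lower() in {".bw", ".bigwig"}:
                rows.append(_read_bigwig(path, chrom, start, end))
            else:
                rows.append(_read_bedgraph(path, chrom, start, end))
        except OSError as exc:
            raise TrackError(
                f"cannot read coverage for sample {s!r}: {path} ({exc})"
            ) from exc
    factors = None
    if project.size_factors is not None:
        factors = np.array([project.size_factors[s] for s in project.samples])
    return CoverageSet(
        chrom, start, end,
        samples=list(project.samples),
        conditions=[project.conditions[s] for s in project.samples],
        matrix=np.vstack(rows),
        size_factors=factors,
    )


def load_junction_table(
    project: ProjectConfig,
    annotation: Iterable[GeneModel] | None = None,
    dialect: str = "minimal_tsv",
) -> JunctionTable:
    """Read every sample's junction file and merge into one table."""
    per_sample = []
    for s in project.samples:
        path = Path(project.junction_paths[s])
        if not path.exists():
            raise TrackError(f"junction file for sample {s!r} missing: {path}")
        per_sample.append((s, read_junction_file(path, dialect)))
    return merge_junction_tables(per_sample, annotation)
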