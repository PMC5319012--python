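"""Seeded simulation of a multi-isoform gene with known splicing truth.

The generator emulates the inputs of the detection pipeline: a gene
model (GTF), per-sample junction counts (minimal TSV or STAR dialect),
per-sample per-base coverage (bedgraph, optionally bigwig) and a project
file — with one or more cassette exons whose per-condition inclusion
level (PSI) is controlled.

Read model per sample ``s`` with library-size factor ``l_s``:

* junction-crossing read totals ``N ~ Poisson(depth * l_s)`` (or the
  rounded mean under the low-noise ``binomial`` model);
* cassette inclusion counts ``~ Binomial(N, PSI_c)``, exclusion is the
  complement of the upstream draw;
* constitutive junctions draw their own ``N``;
* exonic coverage is piecewise constant at the isoform-weighted depth
  (``depth * l_s`` constitutive, ``depth * PSI_c * l_s`` on the
  cassette) plus per-base Poisson noise; introns are 0.

All randomness flows through one ``numpy.random.default_rng(seed)``, so
a scenario is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gene_model import Exon, GeneModel, Transcript, write_gtf
from .track_io import (
    CoverageSet,
    Junction,
    JunctionTable,
    ProjectConfig,
    merge_junction_tables,
    write_junction_file,
    write_project,
)


class SimulationError(ValueError):
    pass


@dataclass
class SimScenario:
    """One simulated two-condition experiment around a cassette-exon gene."""

    seed: int = 0
    n_samples: tuple[int, int] = (3, 3)
    conditions: tuple[str, str] = ("A", "B")
    depth: float = 200.0  # mean junction-crossing reads per sample
    psi: tuple[float, float] = (0.8, 0.3)  # cassette inclusion per condition
    n_exons: int = 5
    exon_length: int = 150
    intron_length: int = 300
    cassette_index: int = 2  # 0-based position of the cassette exon
    gene_start: int = 1000
    chrom: str = "chrS"
    strand: str = "+"
    libsizes: tuple[float, ...] | None = None  # per sample, default all 1
    noise: str = "poisson"  # poisson | binomial (fixed read totals)
    antisense: bool = False  # add an overlapping antisense transcript

    def __post_init__(self):
        if not (0 < self.cassette_index < self.n_exons - 1):
            raise SimulationError("cassette exon must be internal")
        if self.n_exons < 3 or self.exon_length < 1 or self.intron_length < 1:
            raise SimulationError("impossible gene geometry")
        if self.depth <= 0:
            raise SimulationError("depth must be positive")
        if not all(0.0 <= p <= 1.0 for p in self.psi):
            raise SimulationError("PSI values must lie in [0, 1]")
        if self.noise not in {"poisson", "binomial"}:
            raise SimulationError(f"unknown noise model {self.noise!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{cond}{i + 1}"
            for cond, n in zip(self.conditions, self.n_samples)
            for i in range(n)
        ]

    @property
    def sample_conditions(self) -> list[str]:
        return [
            cond for cond, n in zip(self.conditions, self.n_samples)
            for _ in range(n)
        ]

    @property
    def sample_libsizes(self) -> np.ndarray:
        n = sum(self.n_samples)
        if self.libsizes is None:
            return np.ones(n)
        ls = np.asarray(self.libsizes, dtype=float)
        if ls.shape != (n,):
            raise SimulationError("need one libsize per sample")
        return ls


def _exon_coords(scenario: SimScenario) -> list[tuple[int, int]]:
    coords = []
    pos = scenario.gene_start
    for _ in range(scenario.n_exons):
        coords.append((pos, pos + scenario.exon_length))
        pos += scenario.exon_length + scenario.intron_length
    return coords


def simulate_gene(scenario: SimScenario) -> tuple[GeneModel, list[GeneModel]]:
    """Build the gene model: an inclusion isoform with every exon and a
    skipping isoform lacking the cassette exon.

    Returns ``(gene, annotation)`` where annotation contains the gene and
    (optionally) an antisense gene with one exon overlapping a
    constitutive exon of the query gene.
    """
    coords = _exon_coords(scenario)
    chrom = scenario.chrom

    def tx(tx_id: str, idx: list[int]) -> Transcript:
        return Transcript(
            tx_id, chrom, scenario.strand,
            [Exon(chrom, *coords[i], transcript_ids=frozenset({tx_id}))
             for i in idx],
        )

    all_idx = list(range(scenario.n_exons))
    skip_idx = [i for i in all_idx if i != scenario.cassette_index]
    gene = GeneModel(
        "SIMGENE", chrom, scenario.strand,
        [tx("tx_incl", all_idx), tx("tx_skip", skip_idx)],
    )
    annotation = [gene]
    if scenario.antisense:
        anti_strand = "-" if scenario.strand == "+" else "+"
        s, e = coords[0]
        anti = GeneModel(
            "SIMGENE_AS", chrom, anti_strand,
            [Transcript(
                "tx_anti", chrom, anti_strand,
                [Exon(chrom, s + scenario.exon_length // 2,
                      e + scenario.intron_length // 2,
                      transcript_ids=frozenset({"tx_anti"}))],
            )],
        )
        annotation.append(anti)
    return gene, annotation


@dataclass
class SimulatedData:
    """In-memory realization of one scenario."""

    gene: GeneModel
    annotation: list[GeneModel]
    junctions: list[tuple[str, list[tuple[Junction, int]]]]  # per sample
    coverage: CoverageSet
    truth: dict  # cassette meta-exon span and per-condition PSI


def _draw_total(rng: np.random.Generator, mean: float, noise: str) -> int:
    if noise == "poisson":
        return int(rng.poisson(mean))
    return int(round(mean))


def simulate_counts(
    scenario: SimScenario, gene: GeneModel | None = None
) -> SimulatedData:
    """Sample junction counts and coverage for every sample, in memory."""
    if gene is None:
        gene, annotation = simulate_gene(scenario)
    else:
        annotation = [gene]
    rng = np.random.default_rng(scenario.seed)
    coords = _exon_coords(scenario)
    ci = scenario.cassette_index
    chrom = scenario.chrom
    libsizes = scenario.sample_libsizes
    conds = scenario.sample_conditions
    psi_of = dict(zip(scenario.conditions, scenario.psi))

    incl_up = Junction(chrom, coords[ci - 1][1], coords[ci][0])
    incl_down = Junction(chrom, coords[ci][1], coords[ci + 1][0])
    excl = Junction(chrom, coords[ci - 1][1], coords[ci + 1][0])
    constitutive = [
        Junction(chrom, coords[i][1], coords[i + 1][0])
        for i in range(scenario.n_exons - 1)
        if i != ci - 1 and i != ci
    ]

    span_start, span_end = gene.span
    length = span_end - span_start
    per_sample: list[tuple[str, list[tuple[Junction, int]]]] = []
    cov_rows = []
    for s_id, cond, lib in zip(scenario.sample_ids, conds, libsizes):
        psi = psi_of[cond]
        mean = scenario.depth * lib
        entries: list[tuple[Junction, int]] = []
        n1 = _draw_total(rng, mean, scenario.noise)
        k_up = int(rng.binomial(n1, psi)) if n1 else 0
        entries.append((incl_up, k_up))
        entries.append((excl, n1 - k_up))
        n2 = _draw_total(rng, mean, scenario.noise)
        k_down = int(rng.binomial(n2, psi)) if n2 else 0
        entries.append((incl_down, k_down))
        for j in constitutive:
            entries.append((j, _draw_total(rng, mean, scenario.noise)))
        cov = np.zeros(length)
        for i, (es, ee) in enumerate(coords):
            level = mean * (psi if i == ci else 1.0)
            lo, hi = es - span_start, ee - span_start
            if scenario.noise == "poisson":
                cov[lo:hi] = rng.poisson(level, hi - lo)
            else:
                cov[lo:hi] = level
        per_sample.append((s_id, entries))
        cov_rows.append(cov)

    coverage = CoverageSet(
        chrom, span_start, span_end,
        samples=scenario.sample_ids,
        conditions=conds,
        matrix=np.vstack(cov_rows),
    )
    truth = {
        "chrom": chrom,
        "meta_exon_start": coords[ci][0],
        "meta_exon_end": coords[ci][1],
        "psi": dict(zip(scenario.conditions, scenario.psi)),
        "delta_psi": abs(scenario.psi[0] - scenario.psi[1]),
    }
    return SimulatedData(gene, annotation, per_sample, coverage, truth)


def junction_table(data: SimulatedData) -> JunctionTable:
    """Merge the simulated per-sample junction lists, annotation-aware."""
    return merge_junction_tables(data.junctions, data.annotation)


def _write_bedgraph(cov: np.ndarray, chrom: str, start: int, path: Path) -> None:
    lines = []
    i = 0
    n = cov.size
    while i < n:
        j = i
        while j < n and cov[j] == cov[i]:
            j += 1
        if cov[i] != 0:
            lines.append(f"{chrom}\t{start + i}\t{start + j}\t{cov[i]:g}")
        i = j
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _write_bigwig(cov: np.ndarray, chrom: str, start: int, path: Path) -> None:
    import pyBigWig

    bw = pyBigWig.open(str(path), "w")
    chrom_len = start + cov.size + 1000
    bw.addHeader([(chrom, chrom_len)])
    starts, ends, values = [], [], []
    i = 0
    while i < cov.size:
        j = i
        while j < cov.size and cov[j] == cov[i]:
            j += 1
        if cov[i] != 0:
            starts.append(start + i)
            ends.append(start + j)
            values.append(float(cov[i]))
        i = j
    if starts:
        bw.addEntries([chrom] * len(starts), starts, ends=ends, values=values)
    bw.close()


def simulate_reads(
    scenario: SimScenario,
    outdir: str | Path,
    dialect: str = "minimal_tsv",
    coverage_format: str = "bedgraph",
) -> tuple[ProjectConfig, Path, SimulatedData]:
    """Realize a scenario on disk in exactly the pipeline's input formats.

    Writes ``annotation.gtf``, one junction file and one coverage track
    per sample, ``project.tsv`` and ``truth.tsv``.  Returns the project
    config, the annotation path and the in-memory data.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_counts(scenario)
    gtf = outdir / "annotation.gtf"
    write_gtf(data.annotation, gtf)
    ext = {"bedgraph": ".bedgraph", "bigwig": ".bw"}[coverage_format]
    bw_paths: dict[str, Path] = {}
    jc_paths: dict[str, Path] = {}
    for i, (s_id, entries) in enumerate(data.junctions):
        jc = outdir / f"{s_id}.junctions.tsv"
        write_junction_file(entries, jc, dialect)
        jc_paths[s_id] = jc
        track = outdir / f"{s_id}{ext}"
        writer = _write_bigwig if coverage_format == "bigwig" else _write_bedgraph
        writer(data.coverage.matrix[i], scenario.chrom,
               data.coverage.start, track)
        bw_paths[s_id] = track
    project = ProjectConfig(
        samples=scenario.sample_ids,
        conditions=dict(zip(scenario.sample_ids, scenario.sample_conditions)),
        bigwig_paths=bw_paths,
        junction_paths=jc_paths,
    )
    # the written project file uses paths relative to its own directory
    portable = ProjectConfig(
        samples=project.samples,
        conditions=dict(project.conditions),
        bigwig_paths={s: Path(p.name) for s, p in bw_paths.items()},
        junction_paths={s: Path(p.name) for s, p in jc_paths.items()},
    )
    write_project(portable, outdir / "project.tsv")
    truth = data.truth
    (outdir / "truth.tsv").write_text(
        "chrom\tmeta_exon_start\tmeta_exon_end\t"
        + "\t".join(f"psi_{c}" for c in scenario.conditions)
        + "\tdelta_psi\n"
        + f"{truth['chrom']}\t{truth['meta_exon_start']}\t"
        + f"{truth['meta_exon_end']}\t"
        + "\t".join(str(truth["psi"][c]) for c in scenario.conditions)
        + f"\t{truth['delta_psi']}\n"
    )
    return project, gtf, data
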