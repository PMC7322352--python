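"""Ground-truthed synthetic data for the full pipeline.

Emulates the study design the pipeline targets — six groups (three tumor
subtypes, each with a normal-adjacent counterpart), a target tumor group
carrying condition-specific MRE effects — with fully known truth:

* UTR sequences of controlled length and GC with microRNA seed sites planted
  by literal insertion; all flanking sequence is rejection-repaired to be
  free of every site motif (both orientations), so the planted site list IS
  the catalog truth.
* Per-sample read support per planted site drawn from a negative binomial
  with group-specific multipliers on the target-specific rows.
* Error-free reads covering each support event, written as SAM (correct
  coordinates) and FASTQ, so coordinate-mode quantification recovers the
  truth counts exactly and sequence mode agrees.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``; outputs are byte-identical across re-runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import (
    MRECatalog,
    MRESite,
    SeedMotif,
    UTRRecord,
    find_occurrences,
    reverse_complement,
    write_motif_table,
)
from .quantify import MRECountMatrix, SampleLibrary

logger = logging.getLogger(__name__)

DEFAULT_GROUPS = (
    "TN_tumor", "TN_normal",
    "ERpos_tumor", "ERpos_normal",
    "HER2_tumor", "HER2_normal",
)


@dataclass
class SimConfig:
    """Synthetic-study configuration (defaults are the reference conditions)."""

    n_genes: int = 200
    utr_length: tuple[int, int] = (600, 1500)
    gc_range: tuple[float, float] = (0.35, 0.65)
    n_families: int = 50
    families_per_gene: int = 5
    group_labels: tuple[str, ...] = DEFAULT_GROUPS
    n_per_group: int = 13
    target_group: str = "TN_tumor"
    planted_fraction: float = 0.10
    effect_log2fc: float = 3.0
    mu: float = 20.0
    phi: float = 0.2
    read_length: int = 50
    background_reads: float = 0.0
    size_factor_sd: float = 0.15
    spacer: int = 100
    chrom: str = "chr_sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.planted_fraction <= 1):
            raise ValueError("planted_fraction must be in [0, 1]")
        for name in ("n_genes", "n_families", "families_per_gene", "n_per_group",
                     "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu <= 0 or self.phi < 0 or self.effect_log2fc < 0:
            raise ValueError("mu must be > 0, phi and effect_log2fc >= 0")
        if self.families_per_gene > self.n_families:
            raise ValueError("families_per_gene exceeds n_families")
        if self.target_group not in self.group_labels:
            raise ValueError("target_group must be one of group_labels")
        if self.read_length < 8:
            raise ValueError("read length shorter than the longest site")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}_{i + 1:02d}" for g in self.group_labels for i in range(self.n_per_group)]

    def sample_groups(self) -> dict[str, str]:
        return {f"{g}_{i + 1:02d}": g for g in self.group_labels for i in range(self.n_per_group)}


@dataclass
class SimAnnotation:
    """Generated annotation: UTR records, motifs, planted sites, genome."""

    utrs: list[UTRRecord]
    motifs: list[SeedMotif]
    planted_sites: list[MRESite]
    genome: dict[str, str]

    def truth_catalog(self) -> MRECatalog:
        return MRECatalog(self.planted_sites)


_BASES = np.array(list("ACGT"))


def _random_families(cfg: SimConfig, rng: np.random.Generator) -> list[SeedMotif]:
    """Seed motifs whose site sequences (and reverse complements) have no
    substring relation across families or with their own reverse complements,
    so one motif's support can never masquerade as another's."""
    accepted: list[SeedMotif] = []
    pool: list[str] = []  # all accepted site seqs and their revcomps
    attempts = 0
    while len(accepted) < cfg.n_families:
        attempts += 1
        if attempts > 1000 * cfg.n_families:
            raise RuntimeError("could not generate a conflict-free motif set")
        seed7 = "".join(rng.choice(_BASES, size=7))
        fam = SeedMotif(
            family_id=f"mir-{len(accepted) + 1:03d}",
            seed_region=seed7.replace("T", "U"),
        )
        sites = sorted(set(fam.site_seqs.values()))
        rcs = [reverse_complement(s) for s in sites]
        if any(r in s or s in r for s in sites for r in rcs):
            continue
        new = sites + rcs
        if any(a in b or b in a for a in new for b in pool):
            continue
        accepted.append(fam)
        pool.extend(new)
    return accepted


def _exact_gc_flank(n: int, n_gc: int, rng: np.random.Generator) -> np.ndarray:
    """Random base array of length n with exactly n_gc G/C characters."""
    if not 0 <= n_gc <= n:
        raise ValueError("infeasible GC target for requested length")
    arr = np.empty(n, dtype="<U1")
    gc = rng.choice(np.array(["G", "C"]), size=n_gc)
    at = rng.choice(np.array(["A", "T"]), size=n - n_gc)
    arr[:n_gc] = gc
    arr[n_gc:] = at
    rng.shuffle(arr)
    return arr


def _repair_flanks(
    seq: np.ndarray,
    forbidden: Sequence[str],
    protected: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    max_rounds: int = 4000,
) -> None:
    """Swap unprotected bases (GC-preserving) until no forbidden motif occurs
    outside the protected (planted-site) intervals. In place."""
    prot = np.zeros(len(seq), dtype=bool)
    for a, b in protected:
        prot[a:b] = True
    unprot_idx = np.flatnonzero(~prot)

    def first_bad() -> tuple[int, int] | None:
        s = "".join(seq)
        for m in forbidden:
            i = s.find(m)
            while i != -1:
                if not prot[i:i + len(m)].all():
                    return i, i + len(m)
                i = s.find(m, i + 1)
        return None

    for _ in range(max_rounds):
        hit = first_bad()
        if hit is None:
            return
        a, b = hit
        inside = [i for i in range(a, b) if not prot[i]]
        u = int(rng.choice(inside))
        cand = unprot_idx[(unprot_idx < a) | (unprot_idx >= b)]
        cand = cand[seq[cand] != seq[u]]
        if cand.size == 0:
            raise RuntimeError("cannot repair flank: no swappable base")
        v = int(rng.choice(cand))
        seq[u], seq[v] = seq[v], seq[u]
    raise RuntimeError("flank repair did not converge")


def simulate_annotation(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> SimAnnotation:
    """Generate UTRs with planted 8mer sites, motifs, and a synthetic genome.

    Each gene receives ``families_per_gene`` planted 8mer sites (one per
    family), spaced so that no read window of ``read_length`` nt can fully
    contain two sites. Genes alternate strand on a single chromosome
    separated by N spacers.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    motifs = _random_families(cfg, rng)
    forbidden = sorted(
        {s for m in motifs for s in m.site_seqs.values()}
        | {reverse_complement(s) for m in motifs for s in m.site_seqs.values()}
    )
    lo, hi = cfg.utr_length
    m = cfg.families_per_gene
    min_len = m * (2 * cfg.read_length + 8)
    if lo < min_len:
        raise ValueError(
            f"utr_length lower bound {lo} too short for {m} spaced sites "
            f"at read length {cfg.read_length} (need >= {min_len})"
        )
    utrs: list[UTRRecord] = []
    planted: list[MRESite] = []
    genome_parts: list[str] = []
    bed_rows: list[tuple[int, int, str, str]] = []
    cursor = 0
    for gi in range(cfg.n_genes):
        gene = f"gene{gi + 1:04d}"
        L = int(rng.integers(lo, hi + 1))
        gc_t = float(rng.uniform(*cfg.gc_range))
        fams = rng.choice(len(motifs), size=m, replace=False)
        slot = L // m
        offsets = [
            int(si * slot + rng.integers(cfg.read_length, slot - cfg.read_length - 8 + 1))
            for si in range(m)
        ]
        site_seqs = [motifs[int(f)].site_seqs["8mer"] for f in fams]
        n_gc = int(round(gc_t * L))
        gc_in_sites = sum(s.count("G") + s.count("C") for s in site_seqs)
        flank_gc = n_gc - gc_in_sites
        flank_len = L - 8 * m
        if not 0 <= flank_gc <= flank_len:
            raise ValueError(f"{gene}: infeasible GC target {gc_t} for length {L}")
        flank = _exact_gc_flank(flank_len, flank_gc, rng)
        seq = np.empty(L, dtype="<U1")
        prot_ivs = [(p, p + 8) for p in offsets]
        fi = 0
        pi = 0
        pos = 0
        while pos < L:
            if pi < m and pos == offsets[pi]:
                seq[pos:pos + 8] = list(site_seqs[pi])
                pos += 8
                pi += 1
            else:
                nxt = offsets[pi] if pi < m else L
                w = nxt - pos
                seq[pos:pos + w] = flank[fi:fi + w]
                fi += w
                pos = nxt
        _repair_flanks(seq, forbidden, prot_ivs, rng)
        seq_str = "".join(seq)
        strand = "+" if gi % 2 == 0 else "-"
        cursor += cfg.spacer
        start, end = cursor, cursor + L
        cursor = end
        bed_rows.append((start, end, gene, strand))
        genome_parts.append("N" * cfg.spacer)
        genome_parts.append(seq_str if strand == "+" else reverse_complement(seq_str))
        utrs.append(UTRRecord(gene, cfg.chrom, strand, [(start, end)], seq_str))
        for p, f, s in zip(offsets, fams, site_seqs):
            planted.append(MRESite(gene, motifs[int(f)].family_id, "8mer", p, s))
    genome = {cfg.chrom: "".join(genome_parts)}
    return SimAnnotation(utrs, motifs, planted, genome)


def build_truth_table(cfg: SimConfig, ann: SimAnnotation, rng: np.random.Generator) -> pd.DataFrame:
    """Per-(gene, family) truth: baseline mean, planted-effect flag and sign,
    and the per-group mean multiplier."""
    rows = sorted({(s.gene_id, s.family_id) for s in ann.planted_sites})
    n = len(rows)
    n_eff = int(round(cfg.planted_fraction * n))
    eff_idx = rng.choice(n, size=n_eff, replace=False)
    signs = np.zeros(n)
    signs[eff_idx] = rng.choice([-1.0, 1.0], size=n_eff)
    df = pd.DataFrame(rows, columns=["gene_id", "family_id"]).set_index(
        ["gene_id", "family_id"]
    )
    df["baseline_mu"] = cfg.mu
    df["planted"] = signs != 0
    df["effect_sign"] = signs
    for g in cfg.group_labels:
        mult = np.ones(n)
        if g == cfg.target_group:
            mult = 2.0 ** (signs * cfg.effect_log2fc)
        df[f"mult_{g}"] = mult
    return df


def simulate_counts(
    cfg: SimConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator,
    size_factors: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """NB-distributed per-sample counts for every truth row.

    c[g,f,s] ~ NB(mean = mu * mult[group(s)] * sizefactor_s, dispersion phi);
    Poisson when phi = 0. Returns (counts, size factors).
    """
    samples = cfg.sample_ids
    groups = cfg.sample_groups()
    if size_factors is None:
        sf = np.exp(rng.normal(0.0, cfg.size_factor_sd, size=len(samples)))
        size_factors = pd.Series(sf, index=samples, name="size_factor")
    counts = np.empty((len(truth), len(samples)), dtype=int)
    base = truth["baseline_mu"].to_numpy(dtype=float)
    for j, s in enumerate(samples):
        mean = base * truth[f"mult_{groups[s]}"].to_numpy() * float(size_factors[s])
        if cfg.phi == 0:
            counts[:, j] = rng.poisson(mean)
        else:
            r = 1.0 / cfg.phi
            p = r / (r + mean)
            counts[:, j] = rng.negative_binomial(r, p)
    return pd.DataFrame(counts, index=truth.index, columns=samples), size_factors


def counts_to_matrix(cfg: SimConfig, counts: pd.DataFrame) -> MRECountMatrix:
    """Wrap simulated counts as an MRECountMatrix with N_s = column sums
    (every supporting read maps to exactly one UTR; zero background)."""
    groups = cfg.sample_groups()
    libs = [
        SampleLibrary(s, groups[s], int(counts[s].sum())) for s in counts.columns
    ]
    return MRECountMatrix(counts, libs)


def _write_fasta(seqs: dict[str, str], path: Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def simulate_reads(
    cfg: SimConfig,
    ann: SimAnnotation,
    counts: pd.DataFrame,
    outdir: str | Path,
    rng: np.random.Generator,
) -> dict[str, Path]:
    """Write per-sample SAM and FASTQ with error-free reads covering each
    support event (plus optional motif-free background reads)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    utr_by_gene = {u.gene_id: u for u in ann.utrs}
    site_by_pair = {(s.gene_id, s.family_id): s for s in ann.planted_sites}
    R = cfg.read_length
    glen = {c: len(s) for c, s in ann.genome.items()}
    # background windows: positions w where [w, w+R) fully contains no site
    bg_windows: dict[str, np.ndarray] = {}
    if cfg.background_reads > 0:
        for u in ann.utrs:
            sites = [s.utr_offset for s in ann.planted_sites if s.gene_id == u.gene_id]
            ok = np.ones(max(0, u.length - R + 1), dtype=bool)
            for p in sites:
                lo = max(0, p + 8 - R)
                ok[lo:p + 1] = False
            bg_windows[u.gene_id] = np.flatnonzero(ok)
    paths: dict[str, Path] = {}
    header = "@HD\tVN:1.6\tSO:unsorted\n" + "".join(
        f"@SQ\tSN:{c}\tLN:{n}\n" for c, n in glen.items()
    )
    for sample in counts.columns:
        sam_path = outdir / f"{sample}.sam"
        fq_path = outdir / f"{sample}.fastq"
        with open(sam_path, "w") as sam, open(fq_path, "w") as fq:
            sam.write(header)
            for (gene, fam), c in counts[sample].items():
                if c == 0:
                    continue
                u = utr_by_gene[gene]
                p = site_by_pair[(gene, fam)].utr_offset
                w_lo = max(0, p + 8 - R)
                w_hi = min(p, u.length - R)
                ws = rng.integers(w_lo, w_hi + 1, size=int(c))
                for i, w in enumerate(ws):
                    _emit_read(sam, fq, u, int(w), R, f"{sample}:{gene}:{fam}:{i}")
            if cfg.background_reads > 0:
                for u in ann.utrs:
                    n_bg = int(rng.poisson(cfg.background_reads))
                    wins = bg_windows[u.gene_id]
                    if n_bg == 0 or wins.size == 0:
                        continue
                    for i, w in enumerate(rng.choice(wins, size=n_bg)):
                        _emit_read(sam, fq, u, int(w), R, f"{sample}:{u.gene_id}:bg:{i}")
        paths[sample] = sam_path
    return paths


def _emit_read(sam, fq, utr: UTRRecord, w: int, R: int, name: str) -> None:
    seq_t = utr.sequence[w:w + R]
    gstart, gend = utr.intervals[0]
    if utr.strand == "+":
        pos = gstart + w
        flag = 0
        stored = seq_t
    else:
        pos = gend - w - R
        flag = 16
        stored = reverse_complement(seq_t)
    sam.write(
        f"{name}\t{flag}\t{utr.chrom}\t{pos + 1}\t60\t{R}M\t*\t0\t0\t{stored}\t{'I' * R}\n"
    )
    fq.write(f"@{name}\n{seq_t}\n+\n{'I' * R}\n")


def simulate_all(cfg: SimConfig, outdir: str | Path, write_reads: bool = True) -> dict:
    """Run the whole generator and write every pipeline input plus the truth.

    Writes genome FASTA, BED6, motif TSV, sample sheet, truth TSV, per-sample
    SAM/FASTQ (optional), and a config echo JSON. Returns a dict of paths and
    in-memory objects (annotation, truth, counts).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    ann = simulate_annotation(cfg, rng)
    truth = build_truth_table(cfg, ann, rng)
    counts, size_factors = simulate_counts(cfg, truth, rng)

    _write_fasta(ann.genome, outdir / "genome.fa")
    with open(outdir / "utrs.bed", "w") as fh:
        for u in ann.utrs:
            for a, b in u.intervals:
                fh.write(f"{u.chrom}\t{a}\t{b}\t{u.gene_id}\t0\t{u.strand}\n")
    write_motif_table(ann.motifs, outdir / "motifs.tsv")
    groups = cfg.sample_groups()
    pd.DataFrame(
        [(s, groups[s]) for s in cfg.sample_ids], columns=["sample_id", "group"]
    ).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    truth_out = truth.copy()
    offset_by_pair = {(s.gene_id, s.family_id): s.utr_offset for s in ann.planted_sites}
    truth_out["site_offset"] = [offset_by_pair[k] for k in truth.index]
    truth_out.to_csv(outdir / "truth.tsv", sep="\t")
    counts.to_csv(outdir / "truth_counts.tsv", sep="\t")
    size_factors.to_csv(outdir / "size_factors.tsv", sep="\t")
    cfg_dict = asdict(cfg)
    cfg_dict["group_labels"] = list(cfg.group_labels)
    (outdir / "sim_config.json").write_text(json.dumps(cfg_dict, indent=1))
    sam_paths = {}
    if write_reads:
        sam_paths = simulate_reads(cfg, ann, counts, outdir / "reads", rng)
    return {
        "annotation": ann,
        "truth": truth,
        "counts": counts,
        "size_factors": size_factors,
        "fasta": outdir / "genome.fa",
        "bed": outdir / "utrs.bed",
        "motifs": outdir / "motifs.tsv",
        "samples": outdir / "samples.tsv",
        "sam_paths": sam_paths,
    }
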