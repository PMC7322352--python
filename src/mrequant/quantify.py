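"""Read-level MRE quantification.

Counts read support for every (gene, microRNA family) MRE from alignments
overlapping 3'UTRs. Two counting modes are provided:

* ``sequence`` (default) — each read assigned to a gene is scanned for exact
  occurrences of the family's catalog site sequences, by default in both
  orientations (unstranded libraries). This mirrors a BAM -> FASTQ -> motif
  scan design, which discards coordinates.
* ``coordinate`` — a read supports a site when its aligned span fully
  contains the site's genomic interval; paired mates sharing a read id count
  a site once per fragment.

The two modes agree exactly when reads are error-free substrings of the UTR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .catalog import MRECatalog, MRESite, UTRRecord, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class AlignedRead:
    """A mapped read: genomic span plus the stored (forward-genomic) sequence."""

    read_id: str
    chrom: str
    start: int  # 0-based leftmost aligned position
    end: int    # half-open end of aligned span (soft clips excluded)
    seq: str
    is_mate2: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"read {self.read_id}: empty aligned span")


@dataclass
class SampleLibrary:
    """Per-sample library: id, group label, and UTR-restricted library size N_s."""

    sample_id: str
    group_label: str
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size < 0:
            raise ValueError(f"{self.sample_id}: negative library size")


class MRECountMatrix:
    """Raw integer MRE counts, rows (gene_id, family_id) x sample columns."""

    def __init__(self, counts: pd.DataFrame, libraries: Sequence[SampleLibrary]):
        if not counts.index.nlevels == 2:
            raise ValueError("counts must be indexed by (gene_id, family_id)")
        lib_ids = [l.sample_id for l in libraries]
        if sorted(lib_ids) != sorted(counts.columns):
            raise ValueError("library sample ids do not match count columns")
        vals = counts.to_numpy()
        if (vals < 0).any() or not (vals == vals.astype(int)).all():
            raise ValueError("counts must be non-negative integers")
        self.counts = counts.astype(int)
        self.libraries = {l.sample_id: l for l in libraries}

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        return pd.Series(
            {s: self.libraries[s].library_size for s in self.sample_ids}, name="library_size"
        )

    def groups(self) -> pd.Series:
        return pd.Series(
            {s: self.libraries[s].group_label for s in self.sample_ids}, name="group"
        )

    def write_tsv(self, counts_path: str | Path, lib_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        pd.DataFrame(
            [(l.sample_id, l.group_label, l.library_size) for l in self.libraries.values()],
            columns=["sample_id", "group", "library_size"],
        ).to_csv(lib_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, counts_path: str | Path, lib_path: str | Path) -> "MRECountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=[0, 1])
        libs = pd.read_csv(lib_path, sep="\t", dtype={"sample_id": str, "group": str})
        libraries = [
            SampleLibrary(r.sample_id, r.group, int(r.library_size)) for r in libs.itertuples()
        ]
        return cls(counts, libraries)


def iter_sam(path: str | Path) -> Iterator[AlignedRead]:
    """Stream mapped reads from a SAM/BAM file as :class:`AlignedRead`.

    Unmapped, secondary and supplementary records are ignored; unreadable
    records are skipped with a warning (tallied in the log).
    """
    skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            try:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.query_sequence is None or rec.reference_end is None:
                    raise ValueError("missing sequence or alignment span")
                yield AlignedRead(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    seq=rec.query_sequence.upper(),
                    is_mate2=rec.is_read2,
                )
            except (ValueError, TypeError) as e:
                skipped += 1
                logger.warning("skipping unreadable record in %s: %s", path, e)
    if skipped:
        logger.warning("%s: skipped %d unreadable records", path, skipped)


def build_utr_index(utrs: Sequence[UTRRecord]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for u in utrs:
        tree = trees.setdefault(u.chrom, IntervalTree())
        for a, b in u.intervals:
            tree.addi(a, b, u.gene_id)
    return trees


def assign_reads_to_utrs(
    reads: Iterable[AlignedRead],
    utrs: Sequence[UTRRecord],
    min_overlap: int = 1,
    strict_chroms: bool = True,
) -> tuple[dict[str, list[AlignedRead]], int]:
    """Assign each read to every gene whose UTR it overlaps by >= min_overlap nt.

    Returns (gene_id -> reads, N_s) where N_s counts distinct read ids
    assigned to at least one gene (a fragment's two mates share an id and
    count once).
    """
    trees = build_utr_index(utrs)
    by_gene: dict[str, list[AlignedRead]] = {}
    assigned_ids: set[str] = set()
    known_chroms = set(trees)
    for read in reads:
        if read.chrom not in known_chroms:
            if strict_chroms:
                raise ValueError(
                    f"read contig {read.chrom!r} absent from UTR annotation "
                    "(chromosome naming mismatch between alignments and BED?)"
                )
            continue
        hits = set()
        for iv in trees[read.chrom].overlap(read.start, read.end):
            if min(iv.end, read.end) - max(iv.begin, read.start) >= min_overlap:
                hits.add(iv.data)
        for g in hits:
            by_gene.setdefault(g, []).append(read)
        if hits:
            assigned_ids.add(read.read_id)
    return by_gene, len(assigned_ids)


def scan_read(read_seq: str, site_seqs: Iterable[str], unstranded: bool = True) -> int:
    """Count exact site occurrences in a read sequence.

    Every occurrence of every site sequence counts, including overlapping
    ones; in unstranded mode the reverse complement is scanned too, and an
    occurrence present at the same (site, position) in both orientations
    counts once. N never matches.
    """
    if not read_seq:
        return 0
    seq = read_seq.upper()
    L = len(seq)
    occs: set[tuple[str, int]] = set()
    for m in site_seqs:
        i = seq.find(m)
        while i != -1:
            occs.add((m, i))
            i = seq.find(m, i + 1)
    if unstranded:
        rc = reverse_complement(seq)
        for m in site_seqs:
            i = rc.find(m)
            while i != -1:
                occs.add((m, L - i - len(m)))  # map back to forward coordinates
                i = rc.find(m, i + 1)
    return len(occs)


def _site_genomic_span(site: MRESite, utr: UTRRecord) -> tuple[int, int]:
    """Smallest genomic interval containing all of the site's bases."""
    ivs = utr.transcript_to_genomic(site.utr_offset, len(site.site_seq))
    return ivs[0][0], ivs[-1][1]


def quantify_sample(
    reads: Iterable[AlignedRead] | str | Path,
    catalog: MRECatalog,
    utrs: Sequence[UTRRecord],
    sample_id: str,
    mode: str = "sequence",
    stranded: bool = False,
    min_overlap: int = 1,
) -> tuple[pd.Series, int]:
    """Quantify one sample: returns (counts Series indexed by (gene, family), N_s).

    In sequence mode, c[g,f] sums scan_read over reads assigned to g using
    family f's catalog site sequences for that gene. In coordinate mode,
    c[g,f] counts (fragment, site) support events: a fragment supports a site
    when either mate's aligned span contains the site's genomic interval.
    """
    if mode not in ("sequence", "coordinate"):
        raise ValueError(f"unknown counting mode {mode!r}")
    if isinstance(reads, (str, Path)):
        reads = iter_sam(reads)
    utr_by_gene = {u.gene_id: u for u in utrs}
    by_gene, n_s = assign_reads_to_utrs(reads, utrs, min_overlap=min_overlap)
    counts: dict[tuple[str, str], int] = {pair: 0 for pair in catalog.pairs}
    if mode == "sequence":
        # per (gene, family): the retained catalog site sequences on that gene
        seqs_by_pair = {
            pair: sorted({s.site_seq for s in sites})
            for pair, sites in catalog.by_pair.items()
        }
        fams_by_gene: dict[str, list[str]] = {}
        for g, f in catalog.pairs:
            fams_by_gene.setdefault(g, []).append(f)
        for g, greads in by_gene.items():
            utr = utr_by_gene.get(g)
            for f in fams_by_gene.get(g, ()):
                seqs = seqs_by_pair[(g, f)]
                total = 0
                for read in greads:
                    if stranded and utr is not None and utr.strand == "-":
                        total += scan_read(reverse_complement(read.seq), seqs, unstranded=False)
                    else:
                        total += scan_read(read.seq, seqs, unstranded=not stranded)
                counts[(g, f)] = total
    else:
        spans_by_gene: dict[str, list[tuple[str, str, int, int, int]]] = {}
        for s in catalog.sites:
            utr = utr_by_gene.get(s.gene_id)
            if utr is None:
                continue
            a, b = _site_genomic_span(s, utr)
            spans_by_gene.setdefault(s.gene_id, []).append(
                (s.family_id, s.site_type, s.utr_offset, a, b)
            )
        for g, greads in by_gene.items():
            events: set[tuple[str, str, str, int]] = set()  # (read_id, family, gene, offset)
            for read in greads:
                for fam, _stype, off, a, b in spans_by_gene.get(g, ()):
                    if read.start <= a and b <= read.end:
                        events.add((read.read_id, fam, g, off))
            for _rid, fam, gg, _off in events:
                counts[(gg, fam)] += 1
    idx = pd.MultiIndex.from_tuples(catalog.pairs, names=["gene_id", "family_id"])
    col = pd.Series([counts[p] for p in catalog.pairs], index=idx, name=sample_id)
    if n_s == 0:
        logger.warning("sample %s: no reads assigned to any UTR", sample_id)
    return col, n_s


def quantify_samples(
    sample_files: Mapping[str, str | Path],
    groups: Mapping[str, str],
    catalog: MRECatalog,
    utrs: Sequence[UTRRecord],
    mode: str = "sequence",
    stranded: bool = False,
    min_overlap: int = 1,
) -> MRECountMatrix:
    """Quantify a cohort of samples (sample_id -> SAM path) into a count matrix."""
    cols, libs = [], []
    for sample_id in sample_files:
        col, n_s = quantify_sample(
            sample_files[sample_id], catalog, utrs, sample_id,
            mode=mode, stranded=stranded, min_overlap=min_overlap,
        )
        cols.append(col)
        libs.append(SampleLibrary(sample_id, groups[sample_id], n_s))
    return MRECountMatrix(pd.concat(cols, axis=1), libs)


def quantify_from_fastq(
    fastq_path: str | Path,
    assignment: Mapping[str, str],
    catalog: MRECatalog,
    sample_id: str,
    stranded: bool = False,
) -> tuple[pd.Series, int]:
    """Sequence-mode quantification from FASTQ plus a read->gene assignment map.

    Coordinate mode is unavailable without alignments; minus-strand handling
    reduces to unstranded scanning.
    """
    seqs_by_pair = {
        pair: sorted({s.site_seq for s in sites}) for pair, sites in catalog.by_pair.items()
    }
    fams_by_gene: dict[str, list[str]] = {}
    for g, f in catalog.pairs:
        fams_by_gene.setdefault(g, []).append(f)
    counts: dict[tuple[str, str], int] = {pair: 0 for pair in catalog.pairs}
    assigned: set[str] = set()
    with pysam.FastxFile(str(fastq_path)) as fh:
        for rec in fh:
            g = assignment.get(rec.name)
            if g is None:
                continue
            assigned.add(rec.name)
            for f in fams_by_gene.get(g, ()):
                counts[(g, f)] += scan_read(
                    rec.sequence, seqs_by_pair[(g, f)], unstranded=not stranded
                )
    idx = pd.MultiIndex.from_tuples(catalog.pairs, names=["gene_id", "family_id"])
    return pd.Series([counts[p] for p in catalog.pairs], index=idx, name=sample_id), len(assigned)
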