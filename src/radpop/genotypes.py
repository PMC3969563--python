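"""Genotype matrices: VCF ingest, site filtering, RAD-tag grouping, thinning.

The central container is :class:`GenotypeMatrix`, a samples x sites table of
diploid alt-allele dosages (0/1/2, with ``MISSING`` as a distinct sentinel)
together with per-site metadata and per-sample read depth.  Sites include both
variant and invariant (monomorphic) records so that per-site denominators
``L`` used by diversity and divergence statistics are exact; matrices built by
the simulator may instead carry an ``extra_monomorphic`` count standing in for
invariant positions that were never enumerated.

Coordinates are 1-based inclusive (VCF convention) throughout; windowed
operations elsewhere in the package use half-open ``[start, end)`` intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.  Never conflated with dosage 0.
MISSING: int = -1

#: near_indel_bp value meaning "no indel anywhere in the file".
NO_INDEL: int = 2**30

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "near_indel_bp"]


# ---------------------------------------------------------------------------
# containers


@dataclass
class TagLocation:
    """A RAD tag location: the ~144 bp of sequence flanking one cut site.

    ``site_indices`` are integer row positions into the owning matrix's site
    table.  Spans are 1-based inclusive and disjoint within a chromosome.
    """

    tag_id: int
    chrom: str
    start: int
    end: int
    site_indices: list[int] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for ``n_samples`` individuals at ``n_sites`` sites.

    Parameters
    ----------
    sites
        One row per retained site with columns ``chrom, pos, ref, alt, qual,
        near_indel_bp`` (and optionally ``is_exonic``).  Invariant sites carry
        ``alt == "."``.  Rows are sorted by (chrom, pos).
    samples
        Sample sheet with columns ``sample_id, species, location``; row order
        matches the rows of ``G``.
    G
        ``(n_samples, n_sites)`` int8 array of alt-allele dosages, with
        :data:`MISSING` for no-calls.
    depth
        Optional ``(n_samples, n_sites)`` read-depth array.
    extra_monomorphic
        Invariant sites accounted for but not stored as rows (used by the
        simulator, where invariant positions inside tags are implicit).
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    G: np.ndarray
    depth: np.ndarray | None = None
    extra_monomorphic: int = 0
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.G.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"genotype array shape {self.G.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if self.depth is not None and self.depth.shape != self.G.shape:
            raise ValueError("depth array shape does not match genotypes")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_ids in sample sheet")

    # -- dimensions ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.G.shape[0]

    @property
    def n_sites(self) -> int:
        return self.G.shape[1]

    @property
    def is_variant(self) -> np.ndarray:
        """Mask of rows recorded as variant (ALT != '.')."""
        return (self.sites["alt"].to_numpy() != ".")

    @property
    def L(self) -> int:
        """Total analysed sites, variant plus invariant (the denominator of
        per-site statistics)."""
        return self.n_sites + self.extra_monomorphic

    @property
    def S(self) -> int:
        """Segregating sites: variant rows actually polymorphic in ``G``."""
        return int(self.polymorphic_mask().sum())

    @property
    def n_monomorphic_sites(self) -> int:
        return self.L - self.S

    # -- allele bookkeeping -------------------------------------------------

    def alt_counts(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        """Alt-allele count per site over called genotypes."""
        G = self.G if sample_mask is None else self.G[sample_mask]
        return np.where(G == MISSING, 0, G).sum(axis=0)

    def called_chrom_counts(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        """Number of called chromosomes per site (2 x called diploids)."""
        G = self.G if sample_mask is None else self.G[sample_mask]
        return 2 * (G != MISSING).sum(axis=0)

    def allele_freqs(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        """Alt-allele frequency per site (NaN where nothing is called)."""
        ac = self.alt_counts(sample_mask)
        an = self.called_chrom_counts(sample_mask)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, ac / np.maximum(an, 1), np.nan)

    def polymorphic_mask(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        """Sites segregating among the (sub)sample's called genotypes."""
        ac = self.alt_counts(sample_mask)
        an = self.called_chrom_counts(sample_mask)
        return (ac > 0) & (ac < an)

    # -- subsetting ---------------------------------------------------------

    def take_sites(self, index: np.ndarray, extra_monomorphic: int | None = None) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sites=self.sites.iloc[index].reset_index(drop=True),
            samples=self.samples,
            G=self.G[:, index],
            depth=None if self.depth is None else self.depth[:, index],
            extra_monomorphic=(
                self.extra_monomorphic if extra_monomorphic is None else extra_monomorphic
            ),
        )

    def take_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            mask = np.flatnonzero(mask)
        return GenotypeMatrix(
            sites=self.sites,
            samples=self.samples.iloc[mask].reset_index(drop=True),
            G=self.G[mask],
            depth=None if self.depth is None else self.depth[mask],
            extra_monomorphic=self.extra_monomorphic,
        )

    def subset_population(self, pop: str) -> "GenotypeMatrix":
        return self.take_samples(population_mask(self, pop))


def population_mask(m: GenotypeMatrix, pop: str) -> np.ndarray:
    """Boolean sample mask for a population label.

    ``pop`` may name a species, a location, or a ``"species:location"``
    combination.  Raises ``KeyError`` if nothing matches.
    """
    species = m.samples["species"].astype(str).to_numpy()
    location = m.samples["location"].astype(str).to_numpy()
    if ":" in pop:
        sp, loc = pop.split(":", 1)
        mask = (species == sp) & (location == loc)
    else:
        mask = species == pop
        if not mask.any():
            mask = location == pop
    if not mask.any():
        raise KeyError(f"population label {pop!r} matches no samples")
    return mask


# ---------------------------------------------------------------------------
# sample sheet and VCF I/O


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a TSV sample sheet with columns sample_id, species, location."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "species", "location"} - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("sample sheet contains duplicate sample_ids")
    return sheet.reset_index(drop=True)


def read_genotype_matrix(vcf_path, sample_sheet: pd.DataFrame) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    SNP records (including invariant positions written with ``ALT=.``) become
    site rows; multiallelic SNP records are retained with a comma-joined ALT
    and are removed later by :func:`filter_sites`.  Indel records are not
    stored as sites (the analysis is SNP-only) but their positions feed the
    ``near_indel_bp`` annotation.  Symbolic ALT alleles are skipped with a
    logged count.  Column order follows the sample sheet.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    header_samples = list(vcf.samples)
    absent = [s for s in sample_sheet["sample_id"] if s not in header_samples]
    if absent:
        raise ValueError(f"sample sheet samples missing from VCF header: {absent}")
    order = [header_samples.index(s) for s in sample_sheet["sample_id"]]

    rows: list[tuple] = []
    gts: list[np.ndarray] = []
    dps: list[np.ndarray] = []
    indel_positions: dict[str, list[int]] = {}
    n_symbolic = 0

    for v in vcf:
        alts = [a for a in v.ALT]
        if any(a.startswith("<") or a in ("*",) for a in alts):
            n_symbolic += 1
            continue
        is_indel = len(v.REF) != 1 or any(len(a) != 1 for a in alts)
        if is_indel:
            indel_positions.setdefault(v.CHROM, []).append(v.POS)
            continue
        alt = ",".join(alts) if alts else "."
        gt = np.asarray(v.genotypes, dtype=np.int16)[:, :2]
        dosage = np.where((gt < 0).any(axis=1), MISSING, gt.sum(axis=1)).astype(np.int8)
        try:
            dp = v.format("DP")
            dp = np.asarray(dp, dtype=np.int32).reshape(-1)
            dp = np.where(dp < 0, 0, dp)
        except Exception:
            dp = np.zeros(len(header_samples), dtype=np.int32)
        qual = v.QUAL if v.QUAL is not None else np.inf
        rows.append((v.CHROM, v.POS, v.REF, alt, qual))
        gts.append(dosage[order])
        dps.append(dp[order])

    if n_symbolic:
        logger.info("skipped %d records with symbolic ALT alleles", n_symbolic)

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual"])
    sites["near_indel_bp"] = _near_indel_distances(sites, indel_positions)
    G = (
        np.vstack(gts).T.astype(np.int8)
        if gts else np.zeros((len(sample_sheet), 0), dtype=np.int8)
    )
    depth = (
        np.vstack(dps).T.astype(np.int32)
        if dps else np.zeros((len(sample_sheet), 0), dtype=np.int32)
    )
    m = GenotypeMatrix(sites=sites, samples=sample_sheet.reset_index(drop=True), G=G, depth=depth)
    return _sort_sites(m)


def _near_indel_distances(sites: pd.DataFrame, indel_positions: dict) -> np.ndarray:
    out = np.full(len(sites), NO_INDEL, dtype=np.int64)
    for chrom, pos_list in indel_positions.items():
        ipos = np.sort(np.asarray(pos_list))
        mask = (sites["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        spos = sites.loc[mask, "pos"].to_numpy()
        j = np.searchsorted(ipos, spos)
        left = np.where(j > 0, np.abs(spos - ipos[np.maximum(j - 1, 0)]), NO_INDEL)
        right = np.where(j < len(ipos), np.abs(ipos[np.minimum(j, len(ipos) - 1)] - spos), NO_INDEL)
        out[mask] = np.minimum(out[mask], np.minimum(left, right))
    return out


def _sort_sites(m: GenotypeMatrix) -> GenotypeMatrix:
    order = np.lexsort((m.sites["pos"].to_numpy(), m.sites["chrom"].to_numpy()))
    if np.array_equal(order, np.arange(m.n_sites)):
        return m
    return m.take_sites(order)


def write_vcf(m: GenotypeMatrix, path) -> None:
    """Write the matrix as an uncompressed VCF 4.2 with GT:DP genotypes.

    Invariant rows are written with ``ALT=.``; the round trip through
    :func:`read_genotype_matrix` reproduces genotypes exactly.
    """
    chroms = m.sites["chrom"].unique()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=radpop\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.samples["sample_id"])
            + "\n"
        )
        gt_strings = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        mono_gt = {MISSING: "./.", 0: "0/0"}
        for j in range(m.n_sites):
            row = m.sites.iloc[j]
            qual = "." if not np.isfinite(row["qual"]) else f"{row['qual']:g}"
            variant = row["alt"] != "."
            fields = [
                str(row["chrom"]), str(int(row["pos"])), ".", str(row["ref"]),
                str(row["alt"]), qual, "PASS", ".", "GT:DP",
            ]
            lut = gt_strings if variant else mono_gt
            for i in range(m.n_samples):
                dp = 0 if m.depth is None else int(m.depth[i, j])
                fields.append(f"{lut[int(m.G[i, j])]}:{dp}")
            fh.write("\t".join(fields) + "\n")


def write_genotype_table(m: GenotypeMatrix, path) -> None:
    """Write a tidy TSV genotype table (sites x samples dosages)."""
    table = m.sites[["chrom", "pos", "ref", "alt"]].copy()
    for i, sid in enumerate(m.samples["sample_id"]):
        table[sid] = m.G[i]
    table.to_csv(path, sep="\t", index=False)


def write_tag_bed(tags: list[TagLocation], path) -> None:
    """Write tag locations as BED (0-based half-open) with tag_id as name."""
    with open(path, "w") as fh:
        for t in tags:
            fh.write(f"{t.chrom}\t{t.start - 1}\t{t.end}\t{t.tag_id}\n")


# ---------------------------------------------------------------------------
# filtering


def filter_sites(
    m: GenotypeMatrix,
    min_qual: float = 25.0,
    min_depth: int = 15,
    indel_excl_bp: int = 6,
    require_complete: bool = True,
) -> GenotypeMatrix:
    """Apply the site-filter cascade and return a clean matrix.

    Variant sites must be biallelic SNPs with site quality >= ``min_qual``,
    more than ``indel_excl_bp`` bp from the nearest indel, depth >=
    ``min_depth`` in *every* sample, and (when ``require_complete``) no
    missing genotype.  Invariant sites are subject to the same depth and
    completeness rules so the per-site denominator ``L`` stays honest.
    Attrition is recorded per rule in ``filter_log`` (each removed site is
    attributed to the first rule it fails, in the order below).
    """
    n = m.n_sites
    variant = m.is_variant
    multi = np.array([("," in a) for a in m.sites["alt"]], dtype=bool)
    qual = m.sites["qual"].to_numpy(dtype=float)
    near = m.sites["near_indel_bp"].to_numpy(dtype=np.int64)

    fail_multi = variant & multi
    fail_qual = variant & ~fail_multi & (qual < min_qual)
    fail_indel = variant & ~fail_multi & ~fail_qual & (near <= indel_excl_bp)
    so_far = fail_multi | fail_qual | fail_indel

    if m.depth is not None:
        low_depth = (m.depth < min_depth).any(axis=0)
    else:
        low_depth = np.zeros(n, dtype=bool)
    fail_depth = ~so_far & low_depth
    so_far |= fail_depth

    if require_complete:
        fail_missing = ~so_far & (m.G == MISSING).any(axis=0)
    else:
        fail_missing = np.zeros(n, dtype=bool)

    keep = ~(so_far | fail_missing)
    log = {
        "input_sites": int(n),
        "removed_multiallelic": int(fail_multi.sum()),
        "removed_low_quality": int(fail_qual.sum()),
        "removed_near_indel": int(fail_indel.sum()),
        "removed_low_depth": int(fail_depth.sum()),
        "removed_missing": int(fail_missing.sum()),
        "retained_sites": int(keep.sum()),
    }
    for rule, count in log.items():
        logger.info("filter_sites %s = %d", rule, count)
    if keep.sum() == 0:
        logger.warning("filter_sites removed every site")

    out = m.take_sites(keep)
    out.filter_log = log
    return out


# ---------------------------------------------------------------------------
# tag locations


def group_tag_locations(m: GenotypeMatrix, pair_gap_bp: int = 150) -> list[TagLocation]:
    """Partition sites into RAD tag locations.

    Consecutive sites on one chromosome within ``pair_gap_bp`` of the running
    tag span are merged; the default merges the two ~72-bp reads flanking one
    cut site while never bridging the >100 kb between neighbouring cut sites.
    Every site belongs to exactly one tag.
    """
    chroms = m.sites["chrom"].to_numpy()
    pos = m.sites["pos"].to_numpy()
    tags: list[TagLocation] = []
    current: TagLocation | None = None
    for j in range(m.n_sites):
        if (
            current is None
            or chroms[j] != current.chrom
            or pos[j] - current.end > pair_gap_bp
        ):
            current = TagLocation(
                tag_id=len(tags), chrom=chroms[j], start=int(pos[j]), end=int(pos[j])
            )
            tags.append(current)
        current.end = int(pos[j])
        current.site_indices.append(j)
    return tags


def draw_one_snp_per_tag(
    m: GenotypeMatrix, tags: list[TagLocation], seed: int
) -> GenotypeMatrix:
    """Pick one segregating SNP uniformly at random from each tag.

    Tags with no segregating SNP contribute nothing.  The draw is
    deterministic for a fixed seed.  The result carries variant sites only
    (``extra_monomorphic`` is reset: per-site denominators are not meaningful
    for thinned SNP sets).
    """
    rng = np.random.default_rng(seed)
    poly = m.polymorphic_mask() & m.is_variant
    chosen: list[int] = []
    for tag in tags:
        candidates = [j for j in tag.site_indices if poly[j]]
        if candidates:
            chosen.append(candidates[rng.integers(len(candidates))])
    return m.take_sites(np.array(sorted(chosen), dtype=int), extra_monomorphic=0)
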