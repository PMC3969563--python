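"""Hudson-style coalescent generation of RADseq genotype matrices.

The generator produces genotype data with the statistical structure the rest
of the package assumes, and records the generating truth so every analysis
stage can be validated end to end:

* per RAD tag, an independent coalescent genealogy (no recombination within
  the ~144 bp tag, free recombination between tags separated by >100 kb) with
  infinite-sites mutation at rate ``theta_per_tag``;
* single populations with an arbitrary size history
  (:class:`~radpop.demography.DemographicModel`), via time rescaling;
* a three-species complex (one basal species, two recently diverged) with
  island-model location demes inside each species, giving abundant shared
  polymorphism between the close pair and fixed differences to the basal
  species;
* a polymorphic inversion implanted as a two-deme structured coalescent over
  chromosome orientations with low inter-orientation gene flux, which creates
  an island of high LD and divergent haplotype classes;
* divergence-dependent RAD tag dropout, reproducing the loss of tags as more
  divergent samples are added to a data set.

Times are in units of ``2 N_ref`` generations and sizes relative to the
reference (ancestral) population throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from radpop.demography import DemographicModel
from radpop.genotypes import MISSING, NO_INDEL, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "InversionSpec",
    "TruthRecord",
    "simulate_population",
    "simulate_species_complex",
    "implant_inversion",
    "apply_rad_dropout",
]


@dataclass(frozen=True)
class InversionSpec:
    """A segregating inversion: which tags it covers and its dynamics.

    ``freqs`` are the two orientation frequencies (summing to 1); ``m_flux``
    is the scaled gene-flux rate between orientations (gene conversion and
    double crossover), i.e. the per-lineage backward flux rate is
    ``m_flux / 2``.
    """

    chrom: str = "2L"
    n_tags: int = 10
    first_tag: int = 5
    freqs: tuple[float, float] = (0.4, 0.6)
    m_flux: float = 0.1


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults emulate the study conditions.

    ~12 diploids per sampling location, ~144-bp tags every ~130 kb across
    four autosome arms, per-tag scaled mutation rate ~1 (per-site diversity
    of order 0.007), two close species (2 and 3 locations) plus one basal
    species at half the effective size.  The default within-species
    migration (4Nm = 12 with the per-lineage-rate convention, i.e. scaled
    rate 4Nm/2 per lineage) puts pairwise location F_ST at the exact
    two-deme island value 1/(1 + 2*4Nm) = 0.04, the weak differentiation
    regime of the study system.
    """

    seed: int = 0
    n_per_pop: int = 12
    theta_per_tag: float = 1.0
    n_tags: int = 500
    tag_length_bp: int = 144
    tag_spacing_bp: int = 130_000
    chroms: tuple[str, ...] = ("2L", "2R", "3L", "3R")
    demography: DemographicModel = field(default_factory=DemographicModel.standard_neutral)
    # species-complex settings
    species_names: tuple[str, ...] = ("A", "B", "C")
    n_locations: tuple[int, ...] = (2, 3, 1)
    species_sizes: tuple[float, ...] = (1.0, 1.0, 0.5)
    split_recent: float = 0.5
    split_basal: float = 3.0
    migration: float = 12.0       # island-model 4Nm among locations within a species
    inversion: InversionSpec | None = None
    dropout_scale: float = 0.0
    depth: int = 30


@dataclass
class TruthRecord:
    """Everything the generator knows about a simulated data set."""

    config: SimulationConfig
    tag_spans: list[tuple[str, int, int]]
    tag_tmrca: list[float] = field(default_factory=list)
    tag_total_length: list[float] = field(default_factory=list)
    split_times: dict[str, float] | None = None
    karyotypes: dict[str, int] | None = None
    inversion_region: tuple[str, int, int] | None = None
    orientation: np.ndarray | None = None     # per-chromosome labels in region
    n_tags_expected: int = 0


# ---------------------------------------------------------------------------
# genealogy engines


def _single_pop_genealogy(n_chrom: int, model: DemographicModel, rng: np.random.Generator):
    """One coalescent genealogy under a size history.

    Returns (edges, tmrca, total_length); each edge is (leaf_list, length)
    in units of 2 N_ancestral generations.
    """
    tau = 0.0
    lineages = [([i], 0.0) for i in range(n_chrom)]
    edges: list[tuple[list[int], float]] = []
    while len(lineages) > 1:
        k = len(lineages)
        tau += rng.exponential(1.0) / (k * (k - 1) / 2.0)
        t = model.real_time(tau)
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        (leaves_j, birth_j) = lineages.pop(j)
        (leaves_i, birth_i) = lineages.pop(i)
        edges.append((leaves_i, t - birth_i))
        edges.append((leaves_j, t - birth_j))
        lineages.append((leaves_i + leaves_j, t))
    tmrca = lineages[0][1]
    total = sum(e[1] for e in edges)
    return edges, tmrca, total


def _structured_genealogy(
    sample_demes: np.ndarray,
    deme_sizes: dict[int, float],
    mig_groups: dict[int, list[int]],
    mig_rate: float,
    boundaries: list[tuple[float, dict[int, int], dict[int, float], dict[int, list[int]]]],
    rng: np.random.Generator,
):
    """Structured coalescent with piecewise-constant demes.

    ``boundaries`` is a recent-to-past list of (time, deme_remap, new_sizes,
    new_mig_groups) applied as the process crosses each time.  Migration is
    island-model within each group: every lineage leaves its deme at rate
    ``mig_rate / 2``, choosing a uniform other deme of its group.
    Returns (edges, tmrca, total_length).
    """
    t = 0.0
    lineages = [([i], 0.0, int(d)) for i, d in enumerate(sample_demes)]
    edges: list[tuple[list[int], float]] = []
    boundary_idx = 0
    while len(lineages) > 1:
        counts: dict[int, int] = {}
        for _, _, d in lineages:
            counts[d] = counts.get(d, 0) + 1
        coal_rates = {
            d: k * (k - 1) / 2.0 / deme_sizes[d] for d, k in counts.items() if k >= 2
        }
        mig_rates = {
            d: k * mig_rate / 2.0
            for d, k in counts.items()
            if len(mig_groups.get(d, [])) > 0
        }
        total = sum(coal_rates.values()) + sum(mig_rates.values())
        if total > 0:
            dt = rng.exponential(1.0 / total)
        else:
            if boundary_idx >= len(boundaries):
                raise RuntimeError(
                    "structured coalescent stalled: isolated lineages with no "
                    "remaining merge events"
                )
            dt = np.inf
        if boundary_idx < len(boundaries) and t + dt >= boundaries[boundary_idx][0]:
            b_time, remap, new_sizes, new_groups = boundaries[boundary_idx]
            t = b_time
            lineages = [(lv, bt, remap.get(d, d)) for lv, bt, d in lineages]
            deme_sizes = new_sizes
            mig_groups = new_groups
            boundary_idx += 1
            continue
        t += dt
        u = rng.uniform(0.0, total)
        acc = 0.0
        chosen_deme, is_coal = None, False
        for d, r in coal_rates.items():
            acc += r
            if u < acc:
                chosen_deme, is_coal = d, True
                break
        if chosen_deme is None:
            for d, r in mig_rates.items():
                acc += r
                if u < acc:
                    chosen_deme, is_coal = d, False
                    break
        members = [idx for idx, (_, _, d) in enumerate(lineages) if d == chosen_deme]
        if is_coal:
            i, j = rng.choice(len(members), size=2, replace=False)
            ii, jj = sorted((members[int(i)], members[int(j)]))
            leaves_j, birth_j, _ = lineages.pop(jj)
            leaves_i, birth_i, _ = lineages.pop(ii)
            edges.append((leaves_i, t - birth_i))
            edges.append((leaves_j, t - birth_j))
            lineages.append((leaves_i + leaves_j, t, chosen_deme))
        else:
            mover = members[int(rng.integers(len(members)))]
            targets = [d for d in mig_groups[chosen_deme] if d != chosen_deme]
            dest = targets[int(rng.integers(len(targets)))]
            lv, bt, _ = lineages[mover]
            lineages[mover] = (lv, bt, dest)
    tmrca = lineages[0][1]
    return edges, tmrca, sum(e[1] for e in edges)


def _drop_mutations(
    edges: list[tuple[list[int], float]],
    n_chrom: int,
    theta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Infinite-sites mutations: haplotype matrix (n_chrom x S) of 0/1."""
    lengths = np.array([e[1] for e in edges])
    total = lengths.sum()
    n_mut = rng.poisson(theta / 2.0 * total)
    if n_mut == 0:
        return np.zeros((n_chrom, 0), dtype=np.int8)
    which = rng.choice(len(edges), size=n_mut, p=lengths / total)
    H = np.zeros((n_chrom, n_mut), dtype=np.int8)
    for col, e_idx in enumerate(which):
        H[edges[e_idx][0], col] = 1
    return H


def _site_positions(n_sites: int, start: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """Distinct sorted integer positions within a tag span (the span widens in
    the rare case a tag carries more SNPs than base pairs)."""
    span = max(length, n_sites)
    return start + np.sort(rng.choice(span, size=n_sites, replace=False))


def _tag_layout(config: SimulationConfig) -> list[tuple[str, int, int]]:
    per_chrom = int(np.ceil(config.n_tags / len(config.chroms)))
    spans = []
    for c_idx, chrom in enumerate(config.chroms):
        for t in range(per_chrom):
            if len(spans) == config.n_tags:
                break
            start = 1 + t * config.tag_spacing_bp
            spans.append((chrom, start, start + config.tag_length_bp - 1))
    return spans


def _assemble_matrix(
    per_tag_sites: list[tuple[str, np.ndarray, np.ndarray]],
    samples: pd.DataFrame,
    config: SimulationConfig,
    total_tag_bp: int,
) -> GenotypeMatrix:
    """Stack per-tag (chrom, positions, diploid dosages) into one matrix."""
    chroms, positions, gcols = [], [], []
    for chrom, pos, g in per_tag_sites:
        chroms.extend([chrom] * len(pos))
        positions.extend(pos.tolist())
        gcols.append(g)
    G = (
        np.concatenate(gcols, axis=1).astype(np.int8)
        if gcols else np.zeros((len(samples), 0), dtype=np.int8)
    )
    if len(positions):
        sites = pd.DataFrame({
            "chrom": chroms,
            "pos": positions,
            "ref": "A",
            "alt": "T",
            "qual": 99.0,
            "near_indel_bp": NO_INDEL,
        })
        order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
        sites = sites.iloc[order].reset_index(drop=True)
        G = G[:, order]
    else:
        sites = pd.DataFrame(
            {c: pd.Series(dtype=d) for c, d in zip(
                ["chrom", "pos", "ref", "alt", "qual", "near_indel_bp"],
                [object, int, object, object, float, int],
            )}
        )
    depth = np.full(G.shape, config.depth, dtype=np.int32)
    extra = max(total_tag_bp - G.shape[1], 0)
    return GenotypeMatrix(sites=sites, samples=samples, G=G, depth=depth,
                          extra_monomorphic=extra)


# ---------------------------------------------------------------------------
# public generators


def simulate_population(config: SimulationConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """A single panmictic population under ``config.demography``.

    Per tag: one genealogy under the size history, Poisson(theta/2 x total
    branch length) infinite-sites mutations placed uniformly on branches,
    chromosomes paired into diploids.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_pop
    n_chrom = 2 * n
    samples = pd.DataFrame({
        "sample_id": [f"S{i:03d}" for i in range(n)],
        "species": "sim",
        "location": "pop1",
    })
    spans = _tag_layout(config)
    truth = TruthRecord(config=config, tag_spans=spans, n_tags_expected=len(spans))
    per_tag = []
    for chrom, start, end in spans:
        edges, tmrca, total = _single_pop_genealogy(n_chrom, config.demography, rng)
        truth.tag_tmrca.append(tmrca)
        truth.tag_total_length.append(total)
        H = _drop_mutations(edges, n_chrom, config.theta_per_tag, rng)
        pos = _site_positions(H.shape[1], start, config.tag_length_bp, rng)
        G = H[0::2] + H[1::2]
        per_tag.append((chrom, pos, G))
    m = _assemble_matrix(per_tag, samples, config,
                         total_tag_bp=len(spans) * config.tag_length_bp)
    return m, truth


def simulate_species_complex(config: SimulationConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Three species, one basal, with island-model locations inside each.

    Species 0 and 1 split ``split_recent`` ago from a common ancestor which
    split from species 2 ``split_basal`` ago (units of 2 N_ref generations);
    each species is an island model over its locations with scaled migration
    4Nm = ``config.migration``.  Sample-sheet labels are emitted so every
    downstream population operation can address species and locations.
    """
    if not (0 < config.split_recent < config.split_basal):
        raise ValueError("need 0 < split_recent < split_basal")
    rng = np.random.default_rng(config.seed)
    names = config.species_names
    sizes = config.species_sizes

    deme_id = 0
    deme_sizes: dict[int, float] = {}
    mig_groups: dict[int, list[int]] = {}
    rows = []
    sample_demes = []
    species_demes: dict[int, list[int]] = {}
    for s_idx, (name, n_loc, nu) in enumerate(zip(names, config.n_locations, sizes)):
        demes = []
        for loc in range(n_loc):
            deme_sizes[deme_id] = nu
            demes.append(deme_id)
            for i in range(config.n_per_pop):
                rows.append({
                    "sample_id": f"{name}_loc{loc + 1}_{i:02d}",
                    "species": name,
                    "location": f"loc{loc + 1}_{name}",
                })
                sample_demes.extend([deme_id, deme_id])
            deme_id += 1
        species_demes[s_idx] = demes
        for d in demes:
            mig_groups[d] = demes if n_loc > 1 else []
    samples = pd.DataFrame(rows)
    sample_demes = np.array(sample_demes)

    # merge targets: species 0+1 -> ancestral deme X at split_recent;
    # X + species 2 -> root deme at split_basal
    anc12 = deme_id
    root = deme_id + 1
    sizes_mid = {anc12: 1.0, species_demes[2][0]: sizes[2]}
    for d in species_demes[2]:
        sizes_mid[d] = sizes[2]
    remap1 = {d: anc12 for d in species_demes[0] + species_demes[1]}
    groups_mid = {d: species_demes[2] if len(species_demes[2]) > 1 else [] for d in species_demes[2]}
    groups_mid[anc12] = []
    remap2 = {anc12: root}
    remap2.update({d: root for d in species_demes[2]})
    sizes_final = {root: 1.0}
    boundaries = [
        (config.split_recent, remap1, sizes_mid, groups_mid),
        (config.split_basal, remap2, sizes_final, {root: []}),
    ]

    spans = _tag_layout(config)
    truth = TruthRecord(
        config=config, tag_spans=spans, n_tags_expected=len(spans),
        split_times={
            f"{names[0]}|{names[1]}": config.split_recent,
            f"{names[0]}|{names[2]}": config.split_basal,
            f"{names[1]}|{names[2]}": config.split_basal,
        },
    )
    n_chrom = len(sample_demes)
    per_tag = []
    for chrom, start, end in spans:
        edges, tmrca, total = _structured_genealogy(
            sample_demes, dict(deme_sizes), {k: list(v) for k, v in mig_groups.items()},
            config.migration, boundaries, rng,
        )
        truth.tag_tmrca.append(tmrca)
        truth.tag_total_length.append(total)
        H = _drop_mutations(edges, n_chrom, config.theta_per_tag, rng)
        pos = _site_positions(H.shape[1], start, config.tag_length_bp, rng)
        per_tag.append((chrom, pos, H[0::2] + H[1::2]))
    m = _assemble_matrix(per_tag, samples, config,
                         total_tag_bp=len(spans) * config.tag_length_bp)
    return m, truth


def implant_inversion(
    m: GenotypeMatrix,
    truth: TruthRecord,
    spec: InversionSpec | None = None,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Replace a run of tags with inversion-structured genotypes.

    Every sampled chromosome draws an orientation at the configured
    frequencies (one draw per chromosome, shared by all tags in the region --
    this is what creates the island of LD).  Within the region each tag's
    genealogy is a two-deme structured coalescent over orientations with
    deme sizes proportional to orientation frequency and gene-flux rate
    ``m_flux``; at ``m_flux = 0`` the orientation classes never share
    polymorphism.  Karyotype truth (0, 1 or 2 inverted chromosomes per
    sample) is recorded.
    """
    config = truth.config
    spec = spec or config.inversion or InversionSpec()
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)
    region_tags = [
        (c, s, e) for c, s, e in truth.tag_spans if c == spec.chrom
    ][spec.first_tag: spec.first_tag + spec.n_tags]
    if len(region_tags) < 3:
        raise ValueError("inversion region must cover at least 3 tags")
    region = (spec.chrom, region_tags[0][1], region_tags[-1][2])

    n_chrom = 2 * m.n_samples
    orientation = (rng.random(n_chrom) < spec.freqs[0]).astype(int)  # 1 = inverted
    karyo = orientation[0::2] + orientation[1::2]

    deme_sizes = {0: spec.freqs[1], 1: spec.freqs[0]}
    mig_groups = {0: [0, 1], 1: [0, 1]} if spec.m_flux > 0 else {0: [], 1: []}
    # deep cap where the orientation classes share an ancestor (the inversion
    # origin); keeps the m_flux = 0 limit well defined
    cap = [(25.0, {1: 0}, {0: 1.0}, {0: []})]
    per_tag = []
    for chrom, start, end in region_tags:
        edges, _, _ = _structured_genealogy(
            orientation, dict(deme_sizes), {k: list(v) for k, v in mig_groups.items()},
            spec.m_flux, list(cap), rng,
        )
        H = _drop_mutations(edges, n_chrom, config.theta_per_tag, rng)
        pos = _site_positions(H.shape[1], start, config.tag_length_bp, rng)
        per_tag.append((chrom, pos, H[0::2] + H[1::2]))

    # drop original sites inside the region, then splice in the new ones
    chroms = m.sites["chrom"].to_numpy()
    pos = m.sites["pos"].to_numpy()
    inside = (chroms == region[0]) & (pos >= region[1]) & (pos <= region[2])
    kept = m.take_sites(~inside)
    new = _assemble_matrix(per_tag, m.samples, config, total_tag_bp=0)
    sites = pd.concat([kept.sites, new.sites], ignore_index=True)
    G = np.concatenate([kept.G, new.G], axis=1)
    depth = np.full(G.shape, config.depth, dtype=np.int32)
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    out = GenotypeMatrix(
        sites=sites.iloc[order].reset_index(drop=True),
        samples=m.samples, G=G[:, order], depth=depth,
        extra_monomorphic=m.extra_monomorphic,
    )
    new_truth = replace(
        truth,
        karyotypes=dict(zip(m.samples["sample_id"], (int(k) for k in karyo))),
        inversion_region=region,
        orientation=orientation,
    )
    return out, new_truth


def apply_rad_dropout(
    m: GenotypeMatrix,
    truth: TruthRecord,
    scale: float,
    seed: int = 0,
    ref_species: str | None = None,
) -> GenotypeMatrix:
    """Divergence-dependent tag dropout.

    A restriction-site polymorphism destroys a whole tag for a sample, and
    the chance of one grows with divergence from the reference genome.  Each
    (tag, sample) pair is dropped (all its sites set MISSING for that
    sample) with probability ``1 - exp(-scale * d_s)`` where ``d_s`` is the
    expected pairwise coalescent distance of the sample's species to the
    reference species (1 within the reference, ``1 + 2 T_split`` otherwise).
    Complete-case filtering afterwards reproduces the fewer-tags-with-more-
    species pattern of real multi-species RAD data sets.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    out = GenotypeMatrix(
        sites=m.sites.copy(), samples=m.samples, G=m.G.copy(),
        depth=None if m.depth is None else m.depth.copy(),
        extra_monomorphic=m.extra_monomorphic,
    )
    if scale == 0:
        return out
    rng = np.random.default_rng(seed)
    species = m.samples["species"].to_numpy()
    ref = ref_species or species[0]
    div = np.ones(m.n_samples)
    if truth.split_times:
        for i, sp in enumerate(species):
            if sp != ref:
                key = f"{ref}|{sp}"
                rkey = f"{sp}|{ref}"
                t_split = truth.split_times.get(key, truth.split_times.get(rkey, 0.0))
                div[i] = 1.0 + 2.0 * t_split
    p_drop = 1.0 - np.exp(-scale * div)

    chroms = m.sites["chrom"].to_numpy()
    pos = m.sites["pos"].to_numpy()
    for chrom, start, end in truth.tag_spans:
        cols = np.flatnonzero((chroms == chrom) & (pos >= start) & (pos <= end))
        if len(cols) == 0:
            continue
        dropped = rng.random(m.n_samples) < p_drop
        if dropped.any():
            out.G[np.ix_(dropped, cols)] = MISSING
            if out.depth is not None:
                out.depth[np.ix_(dropped, cols)] = 0
    return out
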