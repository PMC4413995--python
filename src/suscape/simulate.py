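"""Synthetic multi-population cohorts for read-depth copy-number analysis.

The generator emulates the statistical structure the pipeline assumes for a
small clade of closely related pig populations: a repeat-masked genome with
autocorrelated GC, a species tree with optional admixture edges, integer
copy-number (CN) landscapes evolving on that tree, GC-biased overdispersed
per-bin read depth, and biallelic genotypes at putatively diploid sites.

Units and conventions
---------------------
* coordinates are 0-based half-open, bins are fixed-width (default 1 kb);
* species-tree branch lengths are in arbitrary "divergence units"; the CN
  event rate and SNP rate are both *per locus (site) per unit branch*, so
  "CN events accumulate 2.5x faster than SNPs" is a statement about the two
  per-unit rates;
* depth is reads per unmasked base, with mean coverage * (CN/2) * g(GC).

Every function is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import Node, Tree

POPULATIONS = ["Sbar", "Sceb", "Scel", "Sver", "Sumatra", "China", "Europe"]

#: Per-individual haploid coverages of the emulated cohort (two individuals
#: per population, 7-18x range).
INDIVIDUAL_COVERAGE = {
    "Sbar": (9.087, 8.087),
    "Sceb": (9.36, 9.174),
    "Scel": (18.409, 7.046),
    "Sver": (9.088, 10.127),
    "Sumatra": (10.961, 11.113),
    "China": (7.965, 11.268),
    "Europe": (7.555, 11.056),
}

_DEFAULT_NEWICK = (
    "((Sumatra:1.0,(China:0.7,Europe:0.7):0.5):1.0,"
    "(Sceb:1.0,(Scel:0.8,(Sbar:0.6,Sver:0.6):0.4):0.4):0.5);"
)


# ---------------------------------------------------------------------------
# genome


@dataclass
class SimulatedGenome:
    """Repeat-masked reference stand-in at bin resolution."""

    chrom_sizes: dict[str, int]
    bin_size: int
    mask: dict[str, np.ndarray]  # (m, 2) 0-based half-open masked intervals
    unmasked: dict[str, np.ndarray]  # unmasked bases per bin
    gc: dict[str, np.ndarray]  # GC fraction of unmasked bases (nan if none)

    def n_bins(self, chrom: str) -> int:
        return len(self.unmasked[chrom])


def simulate_genome(
    chrom_sizes: dict[str, int] | int,
    mask_density: float = 0.35,
    mask_mean_length: float = 800.0,
    bin_size: int = 1000,
    gc_mean: float = 0.42,
    gc_sd: float = 0.05,
    gc_autocorr: float = 0.8,
    seed: int = 0,
) -> SimulatedGenome:
    """Generate a masked genome with per-bin GC.

    Masking alternates exponential unmasked/masked runs so the realised
    masked fraction concentrates on `mask_density`; GC follows a clipped
    AR(1) across bins (autocorrelation `gc_autocorr`).
    """
    if isinstance(chrom_sizes, int):
        chrom_sizes = {"chr1": chrom_sizes}
    if any(size <= 0 for size in chrom_sizes.values()):
        raise ValueError("chromosome sizes must be positive")
    if not 0.0 <= mask_density < 1.0:
        raise ValueError("mask_density must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mask: dict[str, np.ndarray] = {}
    unmasked: dict[str, np.ndarray] = {}
    gc: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        intervals = []
        if mask_density > 0:
            gap_mean = mask_mean_length * (1.0 - mask_density) / mask_density
            pos = 0
            while pos < size:
                pos += int(rng.exponential(gap_mean)) + 1
                if pos >= size:
                    break
                end = min(size, pos + int(rng.exponential(mask_mean_length)) + 1)
                intervals.append((pos, end))
                pos = end
        ivals = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
        mask[chrom] = ivals

        n_bins = (size + bin_size - 1) // bin_size
        masked_per_bin = np.zeros(n_bins, dtype=np.int64)
        for s, e in ivals:
            b0, b1 = s // bin_size, (e - 1) // bin_size
            if b0 == b1:
                masked_per_bin[b0] += e - s
            else:
                masked_per_bin[b0] += (b0 + 1) * bin_size - s
                masked_per_bin[b1] += e - b1 * bin_size
                masked_per_bin[b0 + 1 : b1] += bin_size
        bin_sizes = np.full(n_bins, bin_size, dtype=np.int64)
        bin_sizes[-1] = size - (n_bins - 1) * bin_size
        unmasked[chrom] = bin_sizes - masked_per_bin

        z = np.empty(n_bins)
        z[0] = rng.standard_normal()
        eps = rng.standard_normal(n_bins) * np.sqrt(1.0 - gc_autocorr**2)
        for i in range(1, n_bins):
            z[i] = gc_autocorr * z[i - 1] + eps[i]
        track = np.clip(gc_mean + gc_sd * z, 0.05, 0.95)
        track[unmasked[chrom] == 0] = np.nan
        gc[chrom] = track
    return SimulatedGenome(dict(chrom_sizes), bin_size, mask, unmasked, gc)


# ---------------------------------------------------------------------------
# species history


@dataclass
class SpeciesTree:
    """Rooted species/population tree plus optional admixture edges.

    Admixture edges are (donor, recipient, proportion): at admixture-eligible
    loci the recipient tip copies the donor tip's CN state with the given
    probability, a tip-level shortcut for post-split introgression.
    """

    tree: Tree
    admixture: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for donor, recipient, prop in self.admixture:
            if not 0.0 <= prop <= 1.0:
                raise ValueError("admixture proportion must be in [0, 1]")
        for node in self.tree.edges():
            if node.length is not None and node.length < 0:
                raise ValueError("branch lengths must be >= 0")

    @property
    def taxa(self) -> list[str]:
        return self.tree.leaf_names()


def default_sus_tree(admixture: list[tuple[str, str, float]] | None = None) -> SpeciesTree:
    """Seven-population pig-like history: a *Sus scrofa* clade
    (Sumatra, China, Europe) sister to an island clade (Sceb, Scel, Sbar,
    Sver).  The default admixture edges emulate the repeated glacial-period
    hybridisations of the emulated genus: island Sbar into Sumatra and
    island Sceb into mainland China."""
    if admixture is None:
        admixture = [("Sbar", "Sumatra", 0.3), ("Sceb", "China", 0.2)]
    return SpeciesTree(Tree.from_newick(_DEFAULT_NEWICK), admixture)


def individual_tree(species: SpeciesTree, n_individuals: int = 2, tip_length: float = 0.25, sep: str = "_") -> SpeciesTree:
    """Expand each population tip into `n_individuals` tips ("Pop_1", ...)
    hanging below it, so individual-level CN and genotypes share one tree."""
    tree = species.tree.copy()
    for leaf in tree.leaves():
        pop = leaf.name
        leaf.name = None
        for i in range(1, n_individuals + 1):
            leaf.add(Node(f"{pop}{sep}{i}", tip_length))
    return SpeciesTree(tree, list(species.admixture))


# ---------------------------------------------------------------------------
# truth CN landscapes


@dataclass
class TruthCNLandscape:
    """Ground-truth copy numbers: loci x populations, background CN = 2."""

    loci: pd.DataFrame  # columns chrom, start, end, cls (OR | nonOR)
    cn: np.ndarray  # (n_loci, n_populations) integer CN
    populations: list[str]

    def __post_init__(self) -> None:
        if (self.cn < 0).any():
            raise ValueError("copy numbers must be >= 0")

    def cn_per_bin(self, genome: SimulatedGenome, population: str) -> dict[str, np.ndarray]:
        """Per-bin true CN track for one population (2.0 off-locus)."""
        j = self.populations.index(population)
        out = {}
        for chrom, size in genome.chrom_sizes.items():
            track = np.full(genome.n_bins(chrom), 2.0)
            rows = self.loci[self.loci["chrom"] == chrom]
            for i, (s, e) in zip(rows.index, rows[["start", "end"]].to_numpy()):
                track[s // genome.bin_size : (e + genome.bin_size - 1) // genome.bin_size] = self.cn[i, j]
            out[chrom] = track
        return out


def _place_loci(
    genome: SimulatedGenome,
    n_loci: int,
    rng: np.random.Generator,
    len_bins: tuple[int, int] = (8, 20),
    gap_bins: int = 10,
    min_unmasked: int = 300,
) -> pd.DataFrame:
    """Place non-overlapping, bin-aligned loci inside runs of retained bins
    (>= `min_unmasked` unmasked bases), so repeats never interrupt a locus."""
    slots: list[tuple[str, int, int]] = []  # (chrom, first_bin, run_len)
    for chrom in genome.chrom_sizes:
        ok = genome.unmasked[chrom] >= min_unmasked
        boundaries = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
        for s, e in boundaries.reshape(-1, 2):
            if e - s >= len_bins[0]:
                slots.append((chrom, int(s), int(e - s)))
    records = []
    order = rng.permutation(len(slots))
    for k in order:
        chrom, first, run = slots[k]
        cursor = first
        remaining = run
        while remaining >= len_bins[0] and len(records) < n_loci:
            width = int(rng.integers(len_bins[0], min(len_bins[1], remaining) + 1))
            records.append(
                {
                    "chrom": chrom,
                    "start": cursor * genome.bin_size,
                    "end": (cursor + width) * genome.bin_size,
                }
            )
            cursor += width + gap_bins
            remaining = run - (cursor - first)
        if len(records) >= n_loci:
            break
    if len(records) < n_loci:
        raise ValueError(f"genome too small: placed {len(records)} of {n_loci} loci")
    df = pd.DataFrame(records).sort_values(["chrom", "start"]).reset_index(drop=True)
    return df


def _abstract_loci(n_loci: int) -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": "locus", "start": np.arange(n_loci) * 1000, "end": (np.arange(n_loci) + 1) * 1000}
    )


def _branch_deltas(
    n_events: np.ndarray, rng: np.random.Generator, step: str
) -> np.ndarray:
    """Net CN change per locus given per-locus event counts.

    step="unit": each event is +-1 (tandem gain/loss of a single copy);
    step="block": each event moves CN by +-(2 + Poisson(1)), emulating
    unequal crossing-over duplicating/deleting whole blocks of a multi-copy
    array, so a single event is visible on the binarised (|dCN| >= 2) scale.
    """
    delta = np.zeros(n_events.shape, dtype=np.int64)
    if step == "unit":
        n = n_events
        delta = 2 * rng.binomial(n, 0.5) - n
    elif step == "block":
        hot = np.flatnonzero(n_events > 0)
        for i in hot:
            mags = 2 + rng.poisson(1.0, size=n_events[i])
            signs = rng.choice((-1, 1), size=n_events[i])
            delta[i] = int(np.sum(signs * mags))
    else:
        raise ValueError(f"unknown step kind {step!r}")
    return delta


def evolve_cn_on_tree(
    species: SpeciesTree,
    n_loci: int,
    rate: float = 1.0,
    or_fraction: float = 0.36,
    root_cn: tuple[int, int] = (2, 6),
    step: str = "unit",
    admixture_classes: tuple[str, ...] = ("nonOR",),
    nonor_rate_multiplier: float = 4.0,
    genome: SimulatedGenome | None = None,
    seed: int = 0,
    **locus_kwargs,
) -> TruthCNLandscape:
    """Evolve integer CN along the species tree.

    Events on a branch are Poisson(branch_length * rate) per locus; the root
    CN is uniform on `root_cn`; CN is floored at 0.  Non-OR loci are
    perturbed in two ways that OR loci resist by default: their event rate
    is multiplied by `nonor_rate_multiplier` (fast random drift of
    non-olfactory copy number, which saturates and erodes tree signal) and,
    after tree evolution, admixture edges overwrite the recipient's state
    with the donor's at a `proportion` fraction of eligible loci.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    tips = species.taxa
    if not tips or any(t is None for t in tips):
        raise ValueError("empty or unlabeled species tree")
    rng = np.random.default_rng(seed)
    loci = _place_loci(genome, n_loci, rng, **locus_kwargs) if genome is not None else _abstract_loci(n_loci)
    cls = np.where(rng.random(n_loci) < or_fraction, "OR", "nonOR")
    loci = loci.assign(cls=cls)
    locus_rate = rate * np.where(cls == "nonOR", nonor_rate_multiplier, 1.0)

    root_state = rng.integers(root_cn[0], root_cn[1] + 1, size=n_loci)
    states: dict[int, np.ndarray] = {id(species.tree.root): root_state}
    for node in species.tree.preorder():
        if node is species.tree.root:
            continue
        parent_state = states[id(node.parent)]
        lam = (node.length or 0.0) * locus_rate
        n_events = rng.poisson(lam) if lam.max() > 0 else np.zeros(n_loci, dtype=np.int64)
        delta = _branch_deltas(n_events, rng, step)
        states[id(node)] = np.clip(parent_state + delta, 0, None)

    tip_state = {leaf.name: states[id(leaf)] for leaf in species.tree.leaves()}
    eligible = np.isin(cls, admixture_classes)
    for donor, recipient, prop in species.admixture:
        donors = [t for t in tips if t == donor or t.startswith(donor + "_")]
        recipients = [t for t in tips if t == recipient or t.startswith(recipient + "_")]
        if not donors or not recipients:
            raise ValueError(f"admixture edge {donor}->{recipient} not in tree")
        flow = eligible & (rng.random(n_loci) < prop)
        for r in recipients:
            tip_state[r] = np.where(flow, tip_state[donors[0]], tip_state[r])

    cn = np.column_stack([tip_state[t] for t in tips])
    return TruthCNLandscape(loci, cn, list(tips))


def plant_cn_landscape(
    genome: SimulatedGenome,
    populations: list[str] | None = None,
    n_regions: int = 60,
    len_bins: tuple[int, int] = (8, 20),
    cn_values: tuple[int, ...] = (3, 4, 5, 6),
    min_sd: float = 1.0,
    or_fraction: float = 0.36,
    seed: int = 0,
    **locus_kwargs,
) -> TruthCNLandscape:
    """Plant variable regions with known CN for recovery benchmarks.

    Each region amplifies a random, non-empty, proper subset of populations
    to CN in `cn_values` (others stay diploid) and is rejected until the
    cross-population sample s.d. is >= `min_sd`, so every planted region is
    a genuine variable region the ascertainment rules should find.
    """
    populations = list(populations or POPULATIONS)
    rng = np.random.default_rng(seed)
    loci = _place_loci(genome, n_regions, rng, len_bins=len_bins, **locus_kwargs)
    loci = loci.assign(cls=np.where(rng.random(n_regions) < or_fraction, "OR", "nonOR"))
    n_pop = len(populations)
    cn = np.full((n_regions, n_pop), 2, dtype=np.int64)
    for i in range(n_regions):
        while True:
            k = int(rng.integers(1, n_pop))
            who = rng.choice(n_pop, size=k, replace=False)
            vec = np.full(n_pop, 2, dtype=np.int64)
            vec[who] = rng.choice(cn_values, size=k)
            if np.std(vec, ddof=1) >= min_sd:
                cn[i] = vec
                break
    return TruthCNLandscape(loci, cn, populations)


# ---------------------------------------------------------------------------
# read depth


def default_gc_bias(gc: np.ndarray) -> np.ndarray:
    """Smooth unimodal coverage bias, g(GC) = exp(-4 (GC - 0.45)^2)
    (un-normalised; `simulate_depth_track` rescales to mean 1)."""
    return np.exp(-4.0 * (np.asarray(gc) - 0.45) ** 2)


@dataclass
class ReadDepthSimConfig:
    """Per-individual sequencing model.

    coverage    haploid-genome-pair coverage (reads-per-base at CN 2)
    dispersion  negative-binomial size of per-bin read counts
                (var = mu + mu^2/dispersion; 60 gives the 2-4x Poisson
                overdispersion typical of short-read WGS bins)
    read_length nominal read length used to convert depth to read counts
    gc_bias     multiplicative bias curve over GC (None = default curve)
    """

    coverage: float
    dispersion: float = 60.0
    read_length: int = 100
    gc_bias: object | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


def simulate_depth_track(
    genome: SimulatedGenome,
    truth: TruthCNLandscape | None,
    population: str,
    config: ReadDepthSimConfig,
) -> dict[str, np.ndarray]:
    """Per-bin mean depth for one individual of `population`.

    Bin read counts are negative binomial with mean
    coverage * (CN/2) * g(GC) * unmasked / read_length; depth is
    reads * read_length / unmasked, i.e. a scaled negative binomial whose
    mean is exactly coverage * (CN/2) * g(GC).  Fully masked bins get NaN.
    """
    rng = np.random.default_rng(config.seed)
    bias_fn = config.gc_bias or default_gc_bias
    # normalise the bias curve to mean 1 over bins with any unmasked sequence
    all_gc = np.concatenate([genome.gc[c][genome.unmasked[c] > 0] for c in genome.chrom_sizes])
    scale = float(np.mean(bias_fn(all_gc)))
    if scale <= 0:
        raise ValueError("GC bias curve must be bounded away from 0")
    out = {}
    for chrom in genome.chrom_sizes:
        unm = genome.unmasked[chrom]
        cn = truth.cn_per_bin(genome, population)[chrom] if truth is not None else np.full(len(unm), 2.0)
        g = np.ones(len(unm))
        ok = unm > 0
        g[ok] = bias_fn(genome.gc[chrom][ok]) / scale
        mean_depth = config.coverage * (cn / 2.0) * g
        mu = mean_depth * unm / config.read_length
        reads = np.zeros(len(unm), dtype=np.int64)
        pos = ok & (mu > 0)
        r = config.dispersion
        reads[pos] = rng.negative_binomial(r, r / (r + mu[pos]))
        depth = np.full(len(unm), np.nan)
        depth[ok] = reads[ok] * config.read_length / unm[ok]
        out[chrom] = depth
    return out


# ---------------------------------------------------------------------------
# annotation and calibration inputs


def simulate_genes(
    landscape: TruthCNLandscape,
    genome: SimulatedGenome,
    seed: int = 0,
    gene_prob: float = 0.85,
    frac_range: tuple[float, float] = (0.6, 1.0),
    n_background: int = 40,
) -> pd.DataFrame:
    """Gene models over the truth landscape: most variable loci carry one
    gene of their class covering 60-100% of the locus (so the 70% overlap
    rule has both qualifying and failing cases), plus background genes in
    diploid sequence (class nonOR)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, locus in landscape.loci.iterrows():
        if rng.random() > gene_prob:
            continue
        width = locus["end"] - locus["start"]
        frac = rng.uniform(*frac_range)
        g_len = max(genome.bin_size, int(width * frac))
        g_start = int(locus["start"] + rng.integers(0, width - g_len + 1))
        rows.append(
            {"chrom": locus["chrom"], "start": g_start, "end": g_start + g_len,
             "name": f"G{i:04d}", "cls": locus["cls"]}
        )
    locus_ivals = landscape.loci[["chrom", "start", "end"]]
    for b in range(n_background):
        chrom = list(genome.chrom_sizes)[int(rng.integers(len(genome.chrom_sizes)))]
        size = genome.chrom_sizes[chrom]
        g_len = int(rng.integers(2000, 8001))
        for _ in range(50):
            g_start = int(rng.integers(0, size - g_len))
            same = locus_ivals[locus_ivals["chrom"] == chrom]
            if not ((same["start"] < g_start + g_len) & (same["end"] > g_start)).any():
                rows.append({"chrom": chrom, "start": g_start, "end": g_start + g_len,
                             "name": f"BG{b:03d}", "cls": "nonOR"})
                break
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def simulate_seed_regions(
    genome: SimulatedGenome,
    n_windows: int = 120,
    window_bins: int = 5,
    min_unmasked: int = 300,
    seed: int = 0,
) -> pd.DataFrame:
    """Assumed-diploid seed regions: random windows of retained bins.

    Deliberately not screened against the truth landscape — real orthology-
    based seed sets also contain occasional non-diploid sequence, which the
    second calibration stage is there to absorb."""
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in genome.chrom_sizes:
        ok = np.flatnonzero(genome.unmasked[chrom] >= min_unmasked)
        if len(ok) < window_bins:
            continue
        picks = rng.choice(len(ok) - window_bins, size=n_windows, replace=False)
        for p in picks:
            first = ok[p]
            rows.append(
                {"chrom": chrom, "start": int(first * genome.bin_size),
                 "end": int((first + window_bins) * genome.bin_size)}
            )
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    species: SpeciesTree | Tree,
    n_sites: int,
    snp_rate: float,
    seed: int = 0,
) -> tuple[list[str], np.ndarray]:
    """Biallelic genotypes at diploid sites: each branch flips each site
    with probability branch_length * snp_rate (XOR accumulation), so the
    expected pairwise difference fraction is ~ path length * snp_rate."""
    if n_sites <= 0:
        raise ValueError("n_sites must be > 0")
    tree = species.tree if isinstance(species, SpeciesTree) else species
    rng = np.random.default_rng(seed)
    states: dict[int, np.ndarray] = {id(tree.root): np.zeros(n_sites, dtype=np.uint8)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        p = (node.length or 0.0) * snp_rate
        if p > 0.5:
            raise ValueError("branch_length * snp_rate must be <= 0.5")
        flips = rng.random(n_sites) < p
        states[id(node)] = states[id(node.parent)] ^ flips
    names = tree.leaf_names()
    matrix = np.vstack([states[id(leaf)] for leaf in tree.leaves()])
    return names, matrix
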