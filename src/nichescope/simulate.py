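"""Synthetic multi-omic community generator with known ground truth.

Emulates a weekly-sampled mixed microbial community tracked over a 51-point
time-series: ~78 representative genomes (rMAGs) drawn from four planted
functional types, each type defined by a shared block of KEGG-ortholog (KO)
capabilities on top of a large community-wide core; seasonal abundance
dynamics with one transient disturbance window; metatranscriptome depth equal
to metagenome depth times a type- and condition-dependent activity factor;
Poisson metaproteomic spectral counts driven by transcript depth; and a GC-MS
style metabolomics run with pool/blank quality-control injections and
multiplicative instrument drift.

Every sub-simulation draws from its own pseudo-random stream derived from the
master seed by a fixed offset, so adding a stage never perturbs earlier draws.
Abundances are emitted as depths (not proportions) so the depth-aggregation
paths are exercised downstream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_io

FRACTIONS = ("intra_polar", "intra_nonpolar", "extra_polar", "extra_nonpolar")

FOAM_L1 = [
    "Carbohydrate metabolism",
    "Fatty acid oxidation",
    "TCA cycle",
    "Hydrogen metabolism",
    "Nitrogen cycle",
    "Amino acid utilization",
    "Transporters",
    "Stress response",
    "Cell wall biogenesis",
    "Hydrocarbon degradation",
]

# fixed offsets for the per-stage random streams
_STREAM_REPERTOIRE = 1
_STREAM_TIMESERIES = 2
_STREAM_METABOLOME = 3
_STREAM_TAXONOMY = 4


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic community.

    Defaults mirror the emulated study: 78 rMAGs in 4 functional types over a
    51-point weekly series with 1857 core KOs shared by every type, and a
    transient disturbance window of four consecutive time-points.
    """

    seed: int = 0
    n_rmags: int = 78
    n_types: int = 4
    n_timepoints: int = 51
    ko_universe: int = 9000
    n_core_kos: int = 1857
    # per-type specific block sizes: unequal, as in real communities where
    # one guild has a reduced repertoire; an int means the same size for all
    type_specific_kos: int | tuple[int, ...] = (700, 550, 850, 400)
    # KOs shared by exactly one pair of "neighbouring" types (niche overlap
    # along functional gradients; ring-adjacent pairs share a block)
    pair_shared_kos: int = 300
    # each rMAG carries a uniform-random fraction of its type's block(s),
    # drawn from this range — members of a guild rarely encode its full
    # repertoire, which gives clusters realistic internal spread
    type_block_carriage: tuple[float, float] = (0.6, 1.0)
    private_kos_per_rmag: int = 120
    flip_noise: float = 0.02
    # transient dominance takeover: a few populations spike hard for four
    # consecutive time-points, as in a substrate-pulse community shift
    disturbance_window: tuple[int, int] = (30, 33)  # inclusive index range
    disturbance_spike: float = 20.0
    n_disturbance_rmags: int = 8
    drift_slope: float = 0.01
    pool_every: int = 5
    n_blanks: int = 3
    n_metabolites: int = 65
    n_contaminants: int = 6
    genes_per_rmag: int = 250
    n_contigs_per_rmag: int = 8
    mp_scale: float = 2.0
    conditions: tuple[str, ...] = (
        "in_situ",
        "aerobic",
        "anoxic",
        "aerobic_alternating",
        "anoxic_alternating",
    )

    def __post_init__(self) -> None:
        if isinstance(self.type_specific_kos, int):
            self.type_specific_kos = tuple(
                [self.type_specific_kos] * self.n_types
            )
        elif len(self.type_specific_kos) != self.n_types:
            # recycle or trim the block-size tuple to n_types entries
            reps = -(-self.n_types // len(self.type_specific_kos))
            self.type_specific_kos = tuple(
                (list(self.type_specific_kos) * reps)[: self.n_types]
            )
        n_pairs = len(self.shared_pairs())
        budget = (
            self.n_core_kos
            + sum(self.type_specific_kos)
            + n_pairs * self.pair_shared_kos
        )
        if budget > self.ko_universe:
            raise ValueError(
                "infeasible KO budget: core + type-specific + pair-shared KOs "
                "exceed the universe"
            )
        lo, hi = self.disturbance_window
        if not (0 <= lo <= hi < self.n_timepoints):
            raise ValueError("disturbance_window must lie within the series")
        if not 0.0 <= self.flip_noise <= 1.0:
            raise ValueError("flip_noise must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def shared_pairs(self) -> list[tuple[int, int]]:
        """Type pairs that share an off-core KO block: ring-adjacent pairs."""
        if self.n_types < 2:
            return []
        if self.n_types == 2:
            return [(0, 1)]
        pairs = {
            tuple(sorted((t, (t + 1) % self.n_types))) for t in range(self.n_types)
        }
        return sorted(pairs)


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery tests."""

    type_of_rmag: dict[str, int]
    activity_factor: pd.DataFrame | None = None  # (type, condition) mean MT/MG factor
    ko_activity: dict | None = None  # (type, ko) -> per-condition factor array
    abundance_curve: pd.DataFrame | None = None  # rmag × timepoint depths
    contaminant_metabolites: set[str] = field(default_factory=set)
    drift_curve: dict[str, np.ndarray] = field(default_factory=dict)
    disturbance_rmags: set[str] = field(default_factory=set)
    intra_extra_ratio: pd.DataFrame | None = None


def _ids(prefix: str, n: int, width: int = 5) -> list[str]:
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def simulate_repertoires(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Plant type-structured KO repertoires.

    Each rMAG carries all core KOs, its type's specific block, and a private
    sample from the leftover universe; every cell is then flipped
    independently with probability ``flip_noise``.  Returns the binary
    rMAG × KO presence matrix and the ground truth mapping.
    """
    rng = config.rng(_STREAM_REPERTOIRE)
    rmag_ids = _ids("R", config.n_rmags, width=3)
    ko_ids = np.array(_ids("K", config.ko_universe))
    perm = rng.permutation(config.ko_universe)

    core = perm[: config.n_core_kos]
    blocks = []
    start = config.n_core_kos
    for ty in range(config.n_types):
        size = config.type_specific_kos[ty]
        blocks.append(perm[start : start + size])
        start += size
    pair_blocks: dict[tuple[int, int], np.ndarray] = {}
    for a, b in config.shared_pairs():
        pair_blocks[(a, b)] = perm[start : start + config.pair_shared_kos]
        start += config.pair_shared_kos
    private_pool = perm[start:]

    types = {r: i % config.n_types for i, r in enumerate(rmag_ids)}
    lo_c, hi_c = config.type_block_carriage
    m = np.zeros((config.n_rmags, config.ko_universe), dtype=np.int8)
    for i, r in enumerate(rmag_ids):
        ty = types[r]
        m[i, core] = 1
        f = rng.uniform(lo_c, hi_c)
        blk = blocks[ty]
        n_carry = int(round(f * len(blk)))
        if n_carry:
            m[i, rng.choice(blk, size=n_carry, replace=False)] = 1
        for (a, b), pblk in pair_blocks.items():
            if ty in (a, b) and len(pblk):
                n_carry = int(round(f * len(pblk)))
                if n_carry:
                    m[i, rng.choice(pblk, size=n_carry, replace=False)] = 1
        if config.private_kos_per_rmag and len(private_pool):
            k = min(config.private_kos_per_rmag, len(private_pool))
            m[i, rng.choice(private_pool, size=k, replace=False)] = 1
    if config.flip_noise > 0:
        flips = rng.random(m.shape) < config.flip_noise
        m = np.where(flips, 1 - m, m).astype(np.int8)

    matrix = pd.DataFrame(m, index=pd.Index(rmag_ids, name="rmag_id"), columns=ko_ids)
    matrix = matrix[sorted(matrix.columns)]
    truth = GroundTruth(type_of_rmag=types)
    return matrix, truth


def _seasonal_abundance(config: SimulationConfig, truth: GroundTruth,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Positive seasonal sinusoid × log-normal noise, with a disturbance spike."""
    rmag_ids = list(truth.type_of_rmag)
    t = np.arange(config.n_timepoints)
    period = max(config.n_timepoints, 2)
    base = rng.lognormal(mean=1.0, sigma=0.8, size=len(rmag_ids))
    amp = rng.uniform(0.4, 1.0, size=len(rmag_ids))
    # type-dependent seasonal phase so functional types differ in dynamics
    phase = np.array(
        [2 * np.pi * truth.type_of_rmag[r] / config.n_types for r in rmag_ids]
    ) + rng.normal(0, 0.3, size=len(rmag_ids))
    curves = base[:, None] * np.exp(
        amp[:, None] * np.sin(2 * np.pi * t[None, :] / period + phase[:, None])
    )
    noise = rng.lognormal(mean=0.0, sigma=0.15, size=curves.shape)
    curves = curves * noise

    disturbed = rng.choice(rmag_ids, size=config.n_disturbance_rmags, replace=False)
    lo, hi = config.disturbance_window
    idx = [rmag_ids.index(r) for r in disturbed]
    curves[np.ix_(idx, range(lo, hi + 1))] *= config.disturbance_spike
    truth.disturbance_rmags = set(disturbed)
    return pd.DataFrame(curves, index=pd.Index(rmag_ids, name="rmag_id"),
                        columns=[f"T{j:02d}" for j in t])


def simulate_timeseries(
    config: SimulationConfig,
    matrix: pd.DataFrame,
    truth: GroundTruth,
    condition: str = "in_situ",
) -> dict[str, pd.DataFrame]:
    """Gene- and contig-level MG/MT depth records, MP counts and abiotic factors.

    Gene MG summed depth is proportional to rMAG abundance with gamma noise;
    MT depth equals MG depth times a per-(type, KO, condition) activity
    factor; MP spectral counts are Poisson with mean ``mp_scale`` × MT depth.
    Abiotic factors are linear mixtures of latent substrate signals with a
    substrate spike during the disturbance window.

    Returns a dict with keys: annotations, depth_mg, depth_mt (long gene
    tables), contig_depth_mg, contig_mapping, mp_counts (gene × sample),
    abiotic, manifest, and records ground truth in ``truth``.
    """
    rng = config.rng(_STREAM_TIMESERIES)
    abundance = _seasonal_abundance(config, truth, rng)
    truth.abundance_curve = abundance
    samples = list(abundance.columns)
    rmag_ids = list(abundance.index)
    cond_names = list(config.conditions)
    c_idx = cond_names.index(condition)

    # gene complement: a KO-universe-level subsample of each repertoire.
    # The keep/drop decision is a deterministic function of the KO id, so the
    # same KO columns are retained for every rMAG — gene-level tables stay
    # small while the between-repertoire Jaccard structure is preserved.
    mean_rep = max(float(matrix.values.sum(axis=1).mean()), 1.0)
    keep_frac = min(config.genes_per_rmag / mean_rep, 1.0)
    kept_ko = {
        ko for ko in matrix.columns
        if (zlib.crc32(f"gene-subsample:{ko}".encode()) % 10**6) < keep_frac * 10**6
    }
    gene_rows = []
    for r in rmag_ids:
        kos = [k for k in matrix.columns[matrix.loc[r].values.astype(bool)]
               if k in kept_ko]
        chosen = kos
        lengths = rng.integers(300, 3000, size=len(chosen))
        for j, (ko, ln) in enumerate(zip(chosen, lengths)):
            # ~70% of genes carry a FOAM L1 label, assigned per KO
            # (crc32: stable across processes, unlike str hash)
            h = zlib.crc32(ko.encode())
            foam = FOAM_L1[h % len(FOAM_L1)] if (h % 10) < 7 else ""
            gene_rows.append((f"{r}_g{j:04d}", r, ko, foam, int(ln)))
    annotations = pd.DataFrame(
        gene_rows, columns=core_io.ANNOTATION_COLUMNS
    )

    # per-(type, KO) activity regime shared within a type, varying by condition
    ko_activity: dict[tuple[int, str], np.ndarray] = {}
    for ty in range(config.n_types):
        t_kos = annotations.loc[
            annotations["rmag_id"].map(truth.type_of_rmag) == ty, "ko_id"
        ].unique()
        for ko in t_kos:
            u = rng.random()
            if u < 0.15:
                factors = np.zeros(len(cond_names))  # silent function
            elif u < 0.30:
                factors = rng.uniform(2.0, 4.0, size=len(cond_names))  # highly active
            else:
                factors = rng.lognormal(0.0, 0.4, size=len(cond_names))
            ko_activity[(ty, ko)] = factors
    truth.ko_activity = ko_activity
    act_rows = []
    for ty in range(config.n_types):
        facs = np.array([v for (t2, _), v in ko_activity.items() if t2 == ty])
        for ci, cn in enumerate(cond_names):
            act_rows.append({"type": ty, "condition": cn, "mean_factor": facs[:, ci].mean()})
    truth.activity_factor = pd.DataFrame(act_rows)

    n_genes = len(annotations)
    gene_rmag_idx = annotations["rmag_id"].map(
        {r: i for i, r in enumerate(rmag_ids)}
    ).values
    ab = abundance.values  # rmag × tp
    gamma_shape = 20.0
    mg_depth = ab[gene_rmag_idx, :] * rng.gamma(
        gamma_shape, 1.0 / gamma_shape, size=(n_genes, len(samples))
    )
    act = np.array(
        [
            ko_activity[(truth.type_of_rmag[r], ko)][c_idx]
            for r, ko in zip(annotations["rmag_id"], annotations["ko_id"])
        ]
    )
    mt_depth = mg_depth * act[:, None] * rng.lognormal(
        0.0, 0.1, size=mg_depth.shape
    )
    mp_counts = rng.poisson(config.mp_scale * mt_depth)

    lengths = annotations["length_bp"].values

    def _long(depth: np.ndarray) -> pd.DataFrame:
        df = pd.DataFrame(depth, index=annotations["gene_id"].values, columns=samples)
        long = df.stack().rename("depth").reset_index()
        long.columns = ["feature_id", "sample_id", "depth"]
        ln = long["feature_id"].map(
            dict(zip(annotations["gene_id"], annotations["length_bp"]))
        )
        long["summed_depth"] = long["depth"] * ln
        long["length_bp"] = ln
        return long[core_io.DEPTH_COLUMNS]

    depth_mg = _long(mg_depth)
    depth_mt = _long(mt_depth)

    mp = pd.DataFrame(
        mp_counts, index=pd.Index(annotations["gene_id"].values, name="gene_id"),
        columns=samples,
    )

    # contig-level depth records: abundance split over contigs with mild noise
    contig_rows, map_rows = [], []
    for i, r in enumerate(rmag_ids):
        c_lens = rng.integers(5_000, 200_000, size=config.n_contigs_per_rmag)
        for j, ln in enumerate(c_lens):
            cid = f"{r}_c{j:02d}"
            map_rows.append((cid, r))
            noise = rng.lognormal(0.0, 0.05, size=len(samples))
            for s, sample in enumerate(samples):
                d = ab[i, s] * noise[s]
                contig_rows.append((cid, sample, d * ln, int(ln)))
    contig_depth_mg = pd.DataFrame(contig_rows, columns=core_io.DEPTH_COLUMNS)
    contig_mapping = pd.DataFrame(map_rows, columns=["contig_id", "rmag_id"])

    # abiotic factors: linear mixtures of latent substrate signals
    t = np.arange(config.n_timepoints)
    lo, hi = config.disturbance_window
    latent = np.vstack(
        [
            np.sin(2 * np.pi * t / config.n_timepoints),
            np.cos(2 * np.pi * t / config.n_timepoints),
            np.where((t >= lo) & (t <= hi), 1.0, 0.0),  # substrate spike
        ]
    )
    classes = ["sp", "snp", "pcparams", "pcparams", "ratio", "bp", "bnp", "pcparams"]
    n_fac = len(classes)
    mix = rng.normal(0, 1, size=(n_fac, latent.shape[0]))
    fac_vals = mix @ latent + rng.normal(0, 0.3, size=(n_fac, config.n_timepoints))
    abiotic = pd.DataFrame(
        fac_vals.T, index=samples, columns=[f"factor_{i:02d}" for i in range(n_fac)]
    )
    abiotic.index.name = "sample_id"
    abiotic_meta = pd.DataFrame(
        {
            "factor_id": abiotic.columns,
            "class": classes,
            "source": ["manual" if i % 2 == 0 else "online" for i in range(n_fac)],
        }
    )

    manifest = pd.DataFrame(
        {
            "sample_id": samples,
            "timepoint": list(range(config.n_timepoints)),
            "condition": condition,
        }
    )

    return {
        "annotations": annotations,
        "depth_mg": depth_mg,
        "depth_mt": depth_mt,
        "mg_matrix": pd.DataFrame(mg_depth, index=annotations["gene_id"].values,
                                  columns=samples),
        "mt_matrix": pd.DataFrame(mt_depth, index=annotations["gene_id"].values,
                                  columns=samples),
        "contig_depth_mg": contig_depth_mg,
        "contig_mapping": contig_mapping,
        "mp_counts": mp,
        "abiotic": abiotic,
        "abiotic_meta": abiotic_meta,
        "manifest": manifest,
    }


def pool_positions(n_measurements: int, pool_every: int = 5) -> list[int]:
    """1-based positions of pool injections: after every ``pool_every``-th measurement."""
    return [p for p in range(pool_every, n_measurements + 1, pool_every)]


def simulate_metabolome(
    config: SimulationConfig, truth: GroundTruth
) -> dict[str, dict]:
    """Four-fraction GC-MS style metabolite run with QC structure.

    The measurement sequence interleaves pool samples after every fifth
    measurement and places blanks at the start and end of the run.  All
    intensities are multiplied by a monotone exponential drift curve over the
    instrument sequence.  Planted contaminants appear in blanks at or above
    the 75% rule's removal level.  Ground-truth intracellular/extracellular
    ratios are recorded in ``truth``.

    Returns ``{fraction: {"intensities": metabolite × measurement DataFrame,
    "manifest": DataFrame(measurement_id, position, role, sample_id)}}``.
    """
    rng = config.rng(_STREAM_METABOLOME)
    met_ids = _ids("M", config.n_metabolites, width=3)
    contaminants = set(rng.choice(met_ids, size=config.n_contaminants, replace=False))
    truth.contaminant_metabolites = contaminants

    t = np.arange(config.n_timepoints)
    season = 1.0 + 0.5 * np.sin(
        2 * np.pi * t[None, :] / config.n_timepoints
        + rng.uniform(0, 2 * np.pi, size=(config.n_metabolites, 1))
    )
    base = rng.lognormal(mean=8.0, sigma=1.0, size=config.n_metabolites)

    # shared metabolite-level signal so intra/extra ratios are well defined
    intra_level = base[:, None] * season
    ratio_truth = rng.lognormal(0.0, 0.5, size=config.n_metabolites)
    extra_level = intra_level / ratio_truth[:, None]
    truth.intra_extra_ratio = pd.DataFrame(
        {"metabolite_id": met_ids, "true_ratio": ratio_truth}
    )

    runs: dict[str, dict] = {}
    for fraction in FRACTIONS:
        level = intra_level if fraction.startswith("intra") else extra_level
        level = level * rng.lognormal(0.0, 0.1, size=level.shape)

        # build the instrument sequence: samples with pools interleaved,
        # blanks leading and trailing
        sample_ids = [f"T{j:02d}" for j in t]
        seq: list[tuple[str, str]] = []  # (role, link)
        n_lead = max(1, config.n_blanks - 1)
        for b in range(n_lead):
            seq.append(("blank", f"blank_{b}"))
        si = 0
        for k, sid in enumerate(sample_ids, start=1):
            seq.append(("sample", sid))
            si += 1
            if si % config.pool_every == 0:
                seq.append(("pool", f"pool_{si // config.pool_every}"))
        for b in range(n_lead, config.n_blanks):
            seq.append(("blank", f"blank_{b}"))

        n_meas = len(seq)
        drift = np.exp(config.drift_slope * np.arange(n_meas))
        truth.drift_curve[fraction] = drift

        pool_mean = level.mean(axis=1)  # pools mix all sample extracts
        inten = np.zeros((config.n_metabolites, n_meas))
        detect = rng.random((config.n_metabolites, n_meas)) > 0.05
        for pos, (role, link) in enumerate(seq):
            if role == "sample":
                tp = sample_ids.index(link)
                vals = level[:, tp] * rng.lognormal(0, 0.05, config.n_metabolites)
            elif role == "pool":
                vals = pool_mean * rng.lognormal(0, 0.03, config.n_metabolites)
            else:  # blank: only contaminants carry signal
                vals = np.zeros(config.n_metabolites)
            inten[:, pos] = vals
        # pools must be complete for the prevalence rule; samples may miss
        for pos, (role, _) in enumerate(seq):
            if role == "sample":
                inten[:, pos] *= detect[:, pos]
        # contaminants: blank level at/above sample mean → caught by 75% rule
        sample_cols = [p for p, (role, _) in enumerate(seq) if role == "sample"]
        blank_cols = [p for p, (role, _) in enumerate(seq) if role == "blank"]
        for m_i, m in enumerate(met_ids):
            if m in contaminants:
                smean = inten[m_i, sample_cols].mean()
                inten[m_i, blank_cols] = smean * rng.uniform(1.0, 1.5, len(blank_cols))
        inten = inten * drift[None, :]

        meas_ids = [f"{fraction}_{p:03d}" for p in range(1, n_meas + 1)]
        manifest = pd.DataFrame(
            {
                "measurement_id": meas_ids,
                "position": np.arange(1, n_meas + 1),
                "role": [r for r, _ in seq],
                "sample_id": [l for _, l in seq],
            }
        )
        intensities = pd.DataFrame(
            inten, index=pd.Index(met_ids, name="metabolite_id"), columns=meas_ids
        )
        runs[fraction] = {"intensities": intensities, "manifest": manifest}
    return runs


def simulate_taxonomy(config: SimulationConfig, truth: GroundTruth) -> dict[str, pd.DataFrame]:
    """Synthetic per-marker taxonomic assignments and partial genome-level calls.

    Plumbing for the taxonomy-consensus stage: each planted type maps to a
    lineage; marker-gene assignments vote for the true taxon with high
    probability mass and for a decoy otherwise.
    """
    rng = config.rng(_STREAM_TAXONOMY)
    ranks = ["kingdom", "phylum", "class", "order", "family", "genus"]
    lineages = {
        ty: {r: f"{r}_taxon_{ty}" for r in ranks} for ty in range(config.n_types)
    }
    for ty in lineages:
        lineages[ty]["kingdom"] = "Bacteria"
    marker_rows, genome_rows, truth_rows = [], [], []
    for r, ty in truth.type_of_rmag.items():
        for rank in ranks:
            true_taxon = lineages[ty][rank]
            truth_rows.append((r, rank, true_taxon))
            for m in range(rng.integers(3, 8)):
                if rng.random() < 0.8:
                    taxon = true_taxon
                else:
                    taxon = f"{rank}_decoy_{rng.integers(0, 3)}"
                marker_rows.append(
                    (r, f"marker_{m}", rank, taxon, float(rng.uniform(0.3, 1.0)))
                )
            # genome-level call present for about half the (rmag, rank) pairs
            if rng.random() < 0.5:
                genome_rows.append((r, rank, true_taxon))
    return {
        "markers": pd.DataFrame(
            marker_rows, columns=["rmag_id", "marker_id", "rank", "taxon", "probability"]
        ),
        "genome_tax": pd.DataFrame(genome_rows, columns=["rmag_id", "rank", "taxon"]),
        "true_lineage": pd.DataFrame(truth_rows, columns=["rmag_id", "rank", "taxon"]),
    }


def simulate_quality(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Genome quality table consistent with the rMAG selection rules."""
    rng = config.rng(_STREAM_TAXONOMY + 10)
    rows = []
    for r in truth.type_of_rmag:
        comp = float(np.clip(rng.normal(0.762, 0.08), 0.55, 1.0))
        cont = float(np.clip(rng.normal(0.022, 0.015), 0.0, 0.19))
        rows.append((r, comp, cont, "Bacteria"))
    return pd.DataFrame(rows, columns=core_io.QUALITY_COLUMNS)


def write_dataset(out_dir: str | Path, config: SimulationConfig) -> GroundTruth:
    """Run the full generator and write every TSV schema plus truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_repertoires(config)
    ts = simulate_timeseries(config, matrix, truth)
    runs = simulate_metabolome(config, truth)
    tax = simulate_taxonomy(config, truth)
    quality = simulate_quality(config, truth)

    core_io.write_tsv(ts["annotations"], out / "annotations.tsv")
    core_io.write_tsv(ts["depth_mg"], out / "depth_mg.tsv")
    core_io.write_tsv(ts["depth_mt"], out / "depth_mt.tsv")
    core_io.write_tsv(ts["contig_depth_mg"], out / "contig_depth_mg.tsv")
    core_io.write_tsv(ts["contig_mapping"], out / "contig_mapping.tsv")
    core_io.write_tsv(ts["mp_counts"].reset_index(), out / "mp_counts.tsv")
    core_io.write_tsv(ts["abiotic"].reset_index(), out / "abiotic.tsv")
    core_io.write_tsv(ts["abiotic_meta"], out / "abiotic_meta.tsv")
    core_io.write_tsv(ts["manifest"], out / "manifest.tsv")
    core_io.write_tsv(quality, out / "quality.tsv")
    core_io.write_tsv(tax["markers"], out / "markers.tsv")
    core_io.write_tsv(tax["genome_tax"], out / "genome_tax.tsv")
    for fraction, run in runs.items():
        core_io.write_tsv(run["intensities"].reset_index(), out / f"{fraction}.tsv")
        core_io.write_tsv(run["manifest"], out / f"{fraction}_manifest.tsv")

    tdir = out / "truth"
    tdir.mkdir(exist_ok=True)
    core_io.write_tsv(
        pd.DataFrame(
            {"rmag_id": list(truth.type_of_rmag), "type": list(truth.type_of_rmag.values())}
        ),
        tdir / "types.tsv",
    )
    core_io.write_tsv(truth.abundance_curve.reset_index(), tdir / "abundance.tsv")
    core_io.write_tsv(truth.activity_factor, tdir / "activity_factors.tsv")
    core_io.write_tsv(
        pd.DataFrame({"rmag_id": sorted(truth.disturbance_rmags)}),
        tdir / "disturbance_rmags.tsv",
    )
    core_io.write_tsv(
        pd.DataFrame({"metabolite_id": sorted(truth.contaminant_metabolites)}),
        tdir / "contaminants.tsv",
    )
    core_io.write_tsv(tax["true_lineage"], tdir / "lineage.tsv")
    return truth
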