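"""Genetic-algorithm reconstruction of envelopes from SAXS profiles.

The genome is the latent code of the trained auto-encoder; in free-radius
mode the model radius — the bounding-sphere radius of the decoded shape —
joins as one extra gene, initialized within the physically admissible
range implied by the data's Guinier radius of gyration (capped at 300 A).
Fitness is the chi score between the data and the Zernike-backend profile
of the decoded envelope evaluated at the genome's radius, with soft
penalties holding the search to single connected, properly
size-normalized particles.  The population evolves by tournament
selection, uniform crossover and per-gene Gaussian mutation scaled by the
latent prior's spread, with elitism so the best fit never worsens;
Lamarckian radius refinement anchors each individual's size to the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autoencoder import (RADIUS_MAX, LatentCode, LatentPrior, TrainedCoder,
                          decode_batch)
from .io_formats import InsufficientDataError
from .saxs_compute import (DEFAULT_Q_MAX, N_MAX_DEFAULT, UNIT_BALL_FACTOR,
                           ChiScore, SAXSProfile,
                           _radial_transform_table, chi_score,
                           default_q_grid, zernike_moments, zernike_profile)
from .voxel_shapes import REFERENCE_RADIUS, SCALE_VOX, VoxelGrid

logger = logging.getLogger(__name__)

#: fitness assigned to degenerate (empty-decode or failed) individuals so
#: selection eliminates them without raising
WORST_FITNESS = 1.0e6
#: relative scale of multiplicative radius-gene mutations: the chi basin
#: around the true radius is a few percent wide at any scale, so the
#: mutation step must track the current value rather than stay absolute
RADIUS_MUTATION_REL = 0.10


@dataclass
class Individual:
    genome: LatentCode
    fitness: ChiScore | None = None

    @property
    def chi(self) -> float:
        return self.fitness.value if self.fitness is not None else np.inf


@dataclass
class GAConfig:
    """All knobs of the evolutionary search (see module docstring)."""

    population: int = 100
    generations: int = 100
    elite: int = 5
    tournament: int = 3
    crossover_prob: float = 0.8
    mutation_prob: float = 0.2
    mutation_scale: float = 0.3
    radius_mode: str = "fixed"       # "fixed" | "free"
    radius_value: float = REFERENCE_RADIUS
    #: admissible range for the free radius gene; None = derive from the
    #: data's Guinier Rg (physically, bounding radius ~ 1-2.6 x Rg for
    #: compact through elongated particles) capped at (0, 300] A
    radius_min: float | None = None
    radius_max: float | None = None
    #: fraction of the initial population seeded with encoded synthetic
    #: template shapes (all six families, random geometry); uniform prior
    #: draws decode to amorphous blobs only, so templates give the search
    #: a foothold in every major shape basin
    template_fraction: float = 0.5
    q_max: float = DEFAULT_Q_MAX
    n_max: int = N_MAX_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2 * self.elite:
            raise ValueError("population must be >= 2 * elite")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.radius_mode not in ("fixed", "free"):
            raise ValueError("radius_mode must be 'fixed' or 'free'")
        if self.radius_mode == "fixed" and not (
                0 < self.radius_value <= RADIUS_MAX):
            raise ValueError(f"fixed radius must lie in (0, {RADIUS_MAX}]")


@dataclass
class ReconstructionResult:
    """Outcome of one GA run."""

    best_grid: VoxelGrid
    best_genome: LatentCode
    chi_trajectory: np.ndarray          # generation-best chi
    mean_chi_trajectory: np.ndarray     # population mean chi
    optimized_radius: float
    seed: int
    final_chi: float
    final_population: list = field(default_factory=list)


def initialize_population(prior: LatentPrior, cfg: GAConfig,
                          rng: np.random.Generator | None = None
                          ) -> list[Individual]:
    """Seed the gene pool from the latent prior.

    Latent genes are uniform within the per-dimension [min, max] of the
    prior; in free-radius mode the radius gene is uniform over the
    configured admissible range (default (0, 300) A; ``reconstruct``
    narrows it from the data's Guinier Rg).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo = cfg.radius_min if cfg.radius_min else np.finfo(float).tiny
    hi = cfg.radius_max if cfg.radius_max else RADIUS_MAX
    pop = []
    for _ in range(cfg.population):
        z = rng.uniform(prior.min, prior.max)
        radius = None
        if cfg.radius_mode == "free":
            radius = float(rng.uniform(lo, hi))
        pop.append(Individual(LatentCode(z, radius=radius)))
    return pop


def _genome_radius(ind: Individual, cfg: GAConfig) -> float:
    if cfg.radius_mode == "free" and ind.genome.radius is not None:
        return ind.genome.radius
    return cfg.radius_value


def evaluate_fitness(ind: Individual, coder: TrainedCoder, data: SAXSProfile,
                     cfg: GAConfig) -> ChiScore:
    """Decode -> Zernike profile at the genome's radius -> chi vs data.

    Degenerate decodes (empty grids) and numerical failures get the worst-
    fitness sentinel instead of raising, so a generation never aborts.
    """
    occ = decode_batch(coder, ind.genome.z[None, :])[0]
    ind.fitness = _score_occupancy(occ, _genome_radius(ind, cfg), data, cfg)
    return ind.fitness


def _bound_vox(occ: np.ndarray) -> float:
    """Bounding radius of the occupied set in voxels, translation-invariant.

    Measured about the occupied centroid (scattering does not see where
    the shape sits in the grid, so neither may the size normalization).
    """
    coords = np.argwhere(occ > 0).astype(np.float64)
    coords -= coords.mean(axis=0)
    d = np.sqrt((coords ** 2).sum(axis=1))
    # robust radius: the 98th-percentile distance tracks the bounding
    # sphere within ~2% for compact shapes but is insensitive to thin
    # whiskers, which would otherwise let a small core masquerade as a
    # large model
    return float(np.percentile(d, 98.0))


def _radius_arg(occ: np.ndarray, radius: float) -> float:
    """Profile-evaluation radius such that the occupied set's bounding
    sphere spans ``radius`` Angstrom.

    The radius gene is the *model* radius (bounding sphere of the decoded
    shape).  A decoded envelope that underfills the grid is implicitly
    rescaled to span it, which removes the shape-size degeneracy a raw
    grid-scale radius would create (a small blob at a large grid scale has
    the same physical size as a full-grid shape at a small one).
    """
    from .voxel_shapes import SCALE_VOX
    b = max(_bound_vox(occ), 1.0)
    return radius * SCALE_VOX / b


#: decoded models below this occupied-voxel count are treated as degenerate
MIN_MODEL_VOXELS = 20


def _main_component(occ: np.ndarray) -> np.ndarray:
    """Largest 6-connected component of the occupancy.

    A scattering particle is a single connected body; without this
    constraint sparse disconnected 'dust' decodes (combined with a free
    radius) can mimic almost any smooth profile.
    """
    from scipy import ndimage
    labels, n = ndimage.label(occ,
                              structure=ndimage.generate_binary_structure(3, 1))
    if n <= 1:
        return occ
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return (labels == counts.argmax()).astype(np.uint8)


#: decoded shapes should respect the training normalization (bounding
#: sphere ~ 15 voxel units); the robust bound may drift inside this band
#: without penalty
SIZE_BAND_VOX = (12.5, 15.5)
#: fitness penalty per voxel of size-band violation
SIZE_PENALTY = 2.0


def guinier_rg(data: SAXSProfile, q_rg_max: float = 1.3) -> float | None:
    """Radius of gyration (A) from an iterative Guinier fit at low angle.

    Fits ln I = ln I0 - (Rg^2/3) q^2 on the window q Rg <= ``q_rg_max``,
    re-deriving the window from each new estimate.  Returns None when no
    stable positive estimate exists (e.g. pathological data).
    """
    q2 = data.q ** 2
    positive = data.I > 0
    if positive.sum() < 5:
        return None
    window = data.q <= data.q[min(len(data.q) - 1, max(9, len(data.q) // 3))]
    rg = None
    for _ in range(4):
        sel = positive & window
        if sel.sum() < 5:
            break
        slope, _ = np.polyfit(q2[sel], np.log(data.I[sel]), 1)
        if slope >= 0:
            break
        rg = float(np.sqrt(-3.0 * slope))
        window = data.q * rg <= q_rg_max
    return rg


def _make_scorer(occ: np.ndarray, data: SAXSProfile, cfg: GAConfig):
    """Radius -> ChiScore closure for one decoded shape.

    The expensive, radius-independent work (connected-component cleanup,
    Zernike moments) is done once; scoring a radius then costs only a
    radial-transform interpolation and a chi evaluation.  Decodes whose
    robust bound leaves the training size band [12.5, 15.5] voxels pay a
    soft fitness penalty: this blocks the shape-size degeneracies (tiny
    cores, thin whiskers, disconnected dust) that could otherwise fit any
    smooth profile at a wrong radius.
    """
    occ = _main_component(occ)
    if occ.sum() < MIN_MODEL_VOXELS:
        return None
    b = _bound_vox(occ)
    coords = np.argwhere(occ > 0).astype(np.float64)
    coords -= coords.mean(axis=0)
    rg_vox = float(np.sqrt((coords ** 2).sum(axis=1).mean()))
    mom = zernike_moments(VoxelGrid(occ), n_max=cfg.n_max)
    q = _model_q(data, cfg)
    s_grid, _ = _radial_transform_table(cfg.n_max)
    excess = max(0.0, SIZE_BAND_VOX[0] - b, b - SIZE_BAND_VOX[1])

    def score_at(radius: float) -> ChiScore:
        radius_arg = radius * SCALE_VOX / max(b, 1.0)
        if cfg.q_max * radius_arg * UNIT_BALL_FACTOR > s_grid[-1]:
            # grossly oversized model for this q range
            return ChiScore(value=WORST_FITNESS, scale=0.0)
        try:
            model = zernike_profile(mom, q, radius_arg)
            score = chi_score(model, data, q_max=cfg.q_max)
        except (ValueError, FloatingPointError) as exc:
            logger.warning("fitness evaluation failed (%s); "
                           "assigning sentinel", exc)
            return ChiScore(value=WORST_FITNESS, scale=0.0)
        if excess > 0:
            score = ChiScore(value=score.value + SIZE_PENALTY * excess,
                             scale=score.scale)
        return score

    score_at.bound_vox = b
    score_at.rg_vox = rg_vox
    return score_at


def _score_occupancy(occ: np.ndarray, radius: float, data: SAXSProfile,
                     cfg: GAConfig) -> ChiScore:
    scorer = _make_scorer(occ, data, cfg)
    if scorer is None:
        return ChiScore(value=WORST_FITNESS, scale=0.0)
    return scorer(radius)


def _model_q(data: SAXSProfile, cfg: GAConfig) -> np.ndarray:
    q_hi = min(cfg.q_max, data.q[-1])
    return default_q_grid(q_min=min(0.002, data.q[0]), q_max=q_hi)


def _evaluate_all(pop: list[Individual], coder: TrainedCoder,
                  data: SAXSProfile, cfg: GAConfig,
                  rg_data: float | None = None) -> None:
    """Batch-decode unevaluated individuals; scoring is pure per individual.

    In free-radius mode each individual's radius gene is additionally
    refined in place (Lamarckian): besides the inherited value, the radius
    implied by matching the data's radius of gyration is tried with small
    perturbations, and the best becomes the new gene.  Pure co-evolution
    of shape and radius was measured to stall in deceptive wrong-size
    basins; anchoring the size to the Guinier Rg of the data restores the
    fixed-radius search dynamics that do converge.
    """
    todo = [i for i, ind in enumerate(pop) if ind.fitness is None]
    if not todo:
        return
    Z = np.array([pop[i].genome.z for i in todo])
    occ = decode_batch(coder, Z)
    for j, i in enumerate(todo):
        ind = pop[i]
        scorer = _make_scorer(occ[j], data, cfg)
        if scorer is None:
            ind.fitness = ChiScore(value=WORST_FITNESS, scale=0.0)
            continue
        if cfg.radius_mode != "free" or ind.genome.radius is None                 or rg_data is None:
            ind.fitness = scorer(_genome_radius(ind, cfg))
            continue
        candidates = [ind.genome.radius]
        if scorer.rg_vox > 0:
            # physical Rg of the shape at gene radius R is rg_vox*R/b;
            # match it to the data's Guinier Rg
            r_star = rg_data * scorer.bound_vox / scorer.rg_vox
            candidates += [r_star * f for f in (0.94, 1.0, 1.06)]
        best_r, best = None, None
        for r in candidates:
            r = float(np.clip(r, cfg.radius_min or 1e-6,
                              cfg.radius_max or RADIUS_MAX))
            sc = scorer(r)
            if best is None or sc.value < best.value:
                best_r, best = r, sc
        ind.genome = LatentCode(ind.genome.z, radius=best_r)
        ind.fitness = best


def evolve(pop: list[Individual], cfg: GAConfig, prior: LatentPrior,
           rng: np.random.Generator | None = None) -> list[Individual]:
    """One generation step: elitism + tournament/crossover/mutation.

    Elites (the ``cfg.elite`` best) are copied unchanged with their fitness.
    Offspring come from tournament selection (size ``cfg.tournament``),
    uniform crossover applied with probability ``cfg.crossover_prob``, and
    per-gene Gaussian mutation (probability ``cfg.mutation_prob``, std =
    ``cfg.mutation_scale`` x prior std, clipped back to the prior range;
    the radius gene mutates multiplicatively with ~10% log-normal steps,
    clipped to (0, 300]).
    """
    if any(ind.fitness is None for ind in pop):
        raise ValueError("all individuals must be evaluated before evolve")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ranked = sorted(pop, key=lambda ind: ind.chi)
    nxt: list[Individual] = [
        Individual(ind.genome.copy(), fitness=ind.fitness)
        for ind in ranked[:cfg.elite]
    ]

    def select() -> Individual:
        picks = rng.integers(len(pop), size=cfg.tournament)
        return min((pop[i] for i in picks), key=lambda ind: ind.chi)

    z_std = cfg.mutation_scale * prior.std
    while len(nxt) < cfg.population:
        pa, pb = select(), select()
        za, zb = pa.genome.z.copy(), pb.genome.z.copy()
        ra, rb = pa.genome.radius, pb.genome.radius
        if rng.uniform() < cfg.crossover_prob:
            swap = rng.uniform(size=len(za)) < 0.5
            za[swap], zb[swap] = zb[swap], za[swap].copy()
            if cfg.radius_mode == "free" and rng.uniform() < 0.5:
                ra, rb = rb, ra
        for z, r in ((za, ra), (zb, rb)):
            if len(nxt) >= cfg.population:
                break
            mut = rng.uniform(size=len(z)) < cfg.mutation_prob
            z = z + np.where(mut, rng.normal(size=len(z)) * z_std, 0.0)
            z = np.clip(z, prior.min, prior.max)
            if cfg.radius_mode == "free":
                if rng.uniform() < cfg.mutation_prob:
                    r = r * np.exp(rng.normal() * RADIUS_MUTATION_REL)
                r = float(np.clip(r, cfg.radius_min or 1e-6,
                                  cfg.radius_max or RADIUS_MAX))
            nxt.append(Individual(LatentCode(z, radius=r)))
    return nxt


def refine_radius(occ: np.ndarray, data: SAXSProfile, cfg: GAConfig,
                  n_coarse: int = 48) -> tuple[float, ChiScore]:
    """Best radius for a fixed decoded shape by 1D line search.

    The Zernike moments of the shape do not depend on the radius, so
    scanning the radius costs one radial-transform interpolation per
    candidate.  A geometric coarse grid over (5, 300) A is followed by a
    fine local scan (+/-12% in 2% steps) around the coarse optimum.  Used
    as a memetic refinement of elite individuals in free-radius mode,
    where the chi(radius) basin is only a few percent wide.
    """
    scorer = _make_scorer(occ, data, cfg)
    if scorer is None:
        return REFERENCE_RADIUS, ChiScore(value=WORST_FITNESS, scale=0.0)
    coarse = np.geomspace(5.0, RADIUS_MAX, n_coarse)
    best_r, best = float(coarse[0]), None
    for stage in range(2):
        grid_r = coarse if stage == 0 else best_r * np.arange(0.88, 1.125,
                                                              0.02)
        for r in grid_r:
            if not 0 < r <= RADIUS_MAX:
                continue
            score = scorer(float(r))
            if best is None or score.value < best.value:
                best_r, best = float(r), score
    return best_r, best


def reconstruct(data: SAXSProfile, coder: TrainedCoder, prior: LatentPrior,
                cfg: GAConfig,
                keep_population: bool = False) -> ReconstructionResult:
    """Full GA run: initialize -> (evaluate, evolve) x generations.

    Data are truncated to q <= cfg.q_max before scoring.  Returns the
    best-ever individual decoded at its radius, with per-generation best
    and mean chi trajectories.  Deterministic from cfg.seed.
    """
    if prior.dim != coder.latent_dim:
        raise ValueError("prior dimension does not match the coder")
    data = data.truncated(cfg.q_max)
    if len(data.q) < 5:
        raise InsufficientDataError(
            f"need >= 5 data points at q <= {cfg.q_max}")
    rng = np.random.default_rng(cfg.seed)
    rg_data = guinier_rg(data) if cfg.radius_mode == "free" else None
    if (cfg.radius_mode == "free" and rg_data is not None
            and cfg.radius_min is None and cfg.radius_max is None):
        # physically admissible sizes given the measured Rg: bounding
        # radius ranges from ~Rg (hollow/shell-like) to ~2.6 Rg (very
        # elongated); sizes outside cannot produce the observed Guinier
        # region, and excluding them removes deceptive wrong-size fits
        from dataclasses import replace
        cfg = replace(cfg, radius_min=max(1e-3, 0.9 * rg_data),
                      radius_max=min(RADIUS_MAX, 3.0 * rg_data))
    pop = initialize_population(prior, cfg, rng=rng)
    n_templates = int(round(cfg.template_fraction * cfg.population))
    if n_templates:
        from .voxel_shapes import FAMILIES, ShapeSpec, generate_shape
        from .autoencoder import _encode_batch, _stack
        shapes = [generate_shape(ShapeSpec(FAMILIES[i % len(FAMILIES)],
                                           seed=int(rng.integers(2 ** 31))))
                  for i in range(n_templates)]
        codes = np.concatenate([_encode_batch(coder, _stack(shapes[i:i + 16]))
                                for i in range(0, len(shapes), 16)])
        codes = np.clip(codes.astype(np.float64), prior.min, prior.max)
        for i in range(n_templates):
            pop[i].genome = LatentCode(codes[i], radius=pop[i].genome.radius)
    best_traj, mean_traj = [], []
    best: Individual | None = None
    for gen in range(cfg.generations):
        _evaluate_all(pop, coder, data, cfg, rg_data=rg_data)
        if cfg.radius_mode == "free":
            # memetic step: snap the radius of the best few individuals to
            # the optimum for their decoded shape — the chi(radius) basin
            # is too narrow for blind mutation to land in reliably
            ranked = sorted(range(len(pop)), key=lambda i: pop[i].chi)[:3]
            Z = np.array([pop[i].genome.z for i in ranked])
            occs = decode_batch(coder, Z)
            for j, i in zip(range(len(ranked)), ranked):
                r_best, score = refine_radius(occs[j], data, cfg)
                if score is not None and score.value < pop[i].chi:
                    pop[i].genome = LatentCode(pop[i].genome.z, radius=r_best)
                    pop[i].fitness = score
        gen_best = min(pop, key=lambda ind: ind.chi)
        if best is None or gen_best.chi < best.chi:
            best = Individual(gen_best.genome.copy(), gen_best.fitness)
        best_traj.append(best.chi)
        mean_traj.append(float(np.mean([ind.chi for ind in pop])))
        logger.info("gen %4d  best chi %.4f  mean chi %.4f  radius %.1f",
                    gen, best.chi, mean_traj[-1],
                    _genome_radius(best, cfg))
        if gen < cfg.generations - 1:
            pop = evolve(pop, cfg, prior, rng=rng)
    radius = _genome_radius(best, cfg)
    occ = _main_component(decode_batch(coder, best.genome.z[None, :])[0])
    if occ.sum() == 0:
        occ[15, 15, 15] = 1  # degenerate run: placeholder center voxel
    grid = VoxelGrid(occ, radius=radius)
    return ReconstructionResult(
        best_grid=grid, best_genome=best.genome,
        chi_trajectory=np.array(best_traj),
        mean_chi_trajectory=np.array(mean_traj),
        optimized_radius=radius, seed=cfg.seed, final_chi=best.chi,
        final_population=pop if keep_population else [])


def multi_reconstruct(data: SAXSProfile, coder: TrainedCoder,
                      prior: LatentPrior, cfg: GAConfig,
                      n_runs: int = 10) -> list[ReconstructionResult]:
    """Independent repeated runs with distinct recorded seeds.

    Results are ordered by final chi; each stored seed re-runs its result
    bit-exactly via ``reconstruct``.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    seed_rng = np.random.default_rng(cfg.seed)
    seeds = [int(s) for s in seed_rng.integers(2 ** 31, size=n_runs)]
    results = []
    for s in seeds:
        run_cfg = GAConfig(**{**cfg.__dict__, "seed": s})
        results.append(reconstruct(data, coder, prior, run_cfg))
    return sorted(results, key=lambda r: r.final_chi)


def simulate_profile(grid: VoxelGrid, radius: float | None = None,
                     noise: float = 0.0, seed: int = 0,
                     q: np.ndarray | None = None,
                     n_max: int = N_MAX_DEFAULT) -> SAXSProfile:
    """Synthetic target data: Zernike profile plus Gaussian counting noise.

    Emulates photon-counting statistics: the relative uncertainty grows as
    the intensity falls, sigma(q) = noise * I(q) * sqrt(I(q_min) / I(q)),
    i.e. ``noise`` is the relative error at the lowest angle and weak
    high-q signal is proportionally noisier — the error structure of real
    detector data that makes low q carry the size information.  The
    observed intensity is I(q) * (1 + sigma/I * N(0,1)); with ``noise=0``
    the profile is exact and sigma is omitted.
    """
    if noise < 0:
        raise ValueError("noise level must be non-negative")
    if radius is None:
        radius = grid.radius
    if q is None:
        q = default_q_grid()
    # same conventions as the GA fitness: the particle is the largest
    # connected component and ``radius`` is its bounding-sphere radius
    occ = _main_component(grid.occupancy)
    ideal = zernike_profile(zernike_moments(VoxelGrid(occ), n_max=n_max), q,
                            _radius_arg(occ, radius))
    if noise == 0:
        return ideal
    rng = np.random.default_rng(seed)
    rel = noise * np.sqrt(np.maximum(ideal.I[0] / ideal.I, 1.0))
    I = ideal.I * (1.0 + rel * rng.normal(size=len(q)))
    return SAXSProfile(q, I, sigma=rel * ideal.I)
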