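"""Synthetic-data generators for every pipeline input.

The generators emulate the study designs the pipeline targets:

* an old-vs-young expression matrix with planted differentially expressed
  genes (log2-additive Gaussian noise);
* a compendium of compound-treatment profiles containing planted signature
  reversers, mimickers and exchangeable-noise nulls;
* Gompertz mouse lifespan cohorts with an accelerated-failure treatment
  effect (the treated time axis is scaled, so the mean ratio equals
  ``treatment_effect`` exactly);
* yeast mother-cell budding timelines with lognormal cycle durations and a
  geometric (memoryless per-division death) division count.

Every generator draws from a child RNG seeded as ``(seed, stream)`` with a
fixed per-generator stream id, so adding a generator never perturbs the
output of the others, and a fixed seed reproduces every output bit-for-bit.
Planted-truth labels are always returned alongside the data so recovery
metrics never have to re-derive ground truth.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import BuddingTimeline, ExpressionMatrix, GeneSignature, RankedProfile

__all__ = [
    "SimConfig",
    "gen_expression_groups",
    "gen_compendium",
    "gen_lifespans",
    "gen_budding_timelines",
]

# fixed RNG stream ids, one per generator
_STREAM_EXPRESSION = 0
_STREAM_COMPENDIUM = 1
_STREAM_LIFESPAN = 2
_STREAM_BUDDING = 3


@dataclass(frozen=True)
class SimConfig:
    """Parameters of all synthetic generators.

    Defaults are the study conditions the pipeline is validated under:
    6v6 muscle-style expression groups with 100 planted DE genes at one
    log2 unit over SD 0.3 noise; a 110-compound compendium (100 nulls,
    5 reversers, 5 mimickers at strength 2 over unit-SD profiles);
    Gompertz lifespans with control mean ~394 days, cohort sizes 19 vs 10
    and a 1.216x treatment effect (21.6% extension); 40 yeast mothers with
    ~1.5 h lognormal cycles and a mean replicative lifespan of 25 divisions.
    """

    # expression matrix
    n_genes: int = 1000
    n_young: int = 6
    n_old: int = 6
    n_de_genes: int = 100
    de_log2fc: float = 1.0
    noise_sd: float = 0.3
    # compound compendium
    n_null_compounds: int = 100
    n_reversers: int = 5
    n_mimickers: int = 5
    reversal_strength: float = 2.0
    profile_noise_sd: float = 1.0
    # mouse lifespans (Gompertz hazard a*exp(b*t); shape=b, scale=a, per day)
    lifespan_shape: float = 0.01
    lifespan_scale: float = 1.15e-4
    n_control: int = 19
    n_treated: int = 10
    treatment_effect: float = 1.216
    censor_fraction: float = 0.0
    # yeast budding timelines
    n_mothers: int = 40
    cycle_mu: float = math.log(1.5)
    cycle_sigma: float = 0.25
    mean_divisions: float = 25.0
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_young", "n_old", "n_mothers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("n_de_genes", "n_null_compounds", "n_reversers", "n_mimickers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_de_genes > self.n_genes:
            raise ValueError(
                f"n_de_genes ({self.n_de_genes}) exceeds n_genes ({self.n_genes})"
            )
        if self.noise_sd <= 0 or self.profile_noise_sd <= 0:
            raise ValueError("noise SDs must be > 0")
        if self.lifespan_scale <= 0 or self.lifespan_shape <= 0:
            raise ValueError("Gompertz shape and scale must be > 0")
        if self.treatment_effect <= 0:
            raise ValueError("treatment_effect must be > 0")
        if not 0.0 <= self.censor_fraction < 1.0:
            raise ValueError("censor_fraction must be in [0, 1)")
        if self.cycle_sigma < 0:
            raise ValueError("cycle_sigma must be >= 0")
        if self.mean_divisions < 1:
            raise ValueError("mean_divisions must be >= 1")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def gen_expression_groups(cfg: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a two-group (young vs old) log2 expression matrix.

    Exactly ``cfg.n_de_genes`` genes receive a mean shift of ``de_log2fc``
    in the old group — half up, half down, chosen deterministically from the
    seed — over per-gene baselines with Gaussian noise of SD ``noise_sd``.

    Returns
    -------
    matrix, truth
        ``truth`` has one row per gene with columns ``gene``, ``is_de``,
        ``direction`` (``up``/``down`` meaning higher/lower in old, ``none``
        for nulls).
    """
    rng = _rng(cfg, _STREAM_EXPRESSION)
    genes = _gene_ids(cfg.n_genes)
    samples = [f"young_{i + 1}" for i in range(cfg.n_young)] + [
        f"old_{i + 1}" for i in range(cfg.n_old)
    ]
    design = pd.Series(
        ["young"] * cfg.n_young + ["old"] * cfg.n_old, index=samples, name="group"
    )

    baseline = rng.normal(8.0, 2.0, size=cfg.n_genes)
    de_idx = rng.choice(cfg.n_genes, size=cfg.n_de_genes, replace=False)
    n_up = cfg.n_de_genes - cfg.n_de_genes // 2
    shift = np.zeros(cfg.n_genes)
    shift[de_idx[:n_up]] = cfg.de_log2fc
    shift[de_idx[n_up:]] = -cfg.de_log2fc

    mean = np.tile(baseline[:, None], (1, len(samples)))
    mean[:, cfg.n_young:] += shift[:, None]
    values = mean + rng.normal(0.0, cfg.noise_sd, size=mean.shape)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        design=design,
    )
    direction = np.where(shift > 0, "up", np.where(shift < 0, "down", "none"))
    truth = pd.DataFrame(
        {"gene": genes, "is_de": shift != 0, "direction": direction}
    )
    return matrix, truth


def gen_compendium(
    cfg: SimConfig,
    signature: GeneSignature,
    genes: list[str] | None = None,
) -> tuple[list[RankedProfile], pd.DataFrame]:
    """Simulate a compound-profile compendium with planted truth.

    Each profile assigns every gene of the universe an i.i.d. Gaussian
    differential score (SD ``profile_noise_sd``). Reversers additionally
    shift signature-up genes down and signature-down genes up by
    ``reversal_strength``; mimickers shift in the signature's own direction;
    nulls are pure exchangeable noise.

    Parameters
    ----------
    genes
        The gene universe every profile covers. Defaults to the same
        synthetic universe ``gen_expression_groups`` uses; signature genes
        must be a subset.

    Returns
    -------
    profiles, truth
        ``truth`` has columns ``compound_id`` and ``role`` in
        ``{"null", "reverser", "mimicker"}``.
    """
    if not signature.up or not signature.down:
        raise ValueError("signature must have nonempty up and down sets")
    if genes is None:
        genes = _gene_ids(cfg.n_genes)
    universe = set(genes)
    missing = signature.genes - universe
    if missing:
        raise ValueError(f"signature genes outside gene universe: {sorted(missing)[:5]}")

    rng = _rng(cfg, _STREAM_COMPENDIUM)
    gene_arr = np.asarray(genes)
    up_mask = np.isin(gene_arr, sorted(signature.up))
    down_mask = np.isin(gene_arr, sorted(signature.down))

    roles = (
        [("null", i) for i in range(cfg.n_null_compounds)]
        + [("reverser", i) for i in range(cfg.n_reversers)]
        + [("mimicker", i) for i in range(cfg.n_mimickers)]
    )
    profiles: list[RankedProfile] = []
    records: list[dict] = []
    for role, i in roles:
        scores = rng.normal(0.0, cfg.profile_noise_sd, size=len(gene_arr))
        if role == "reverser":
            scores[up_mask] -= cfg.reversal_strength
            scores[down_mask] += cfg.reversal_strength
        elif role == "mimicker":
            scores[up_mask] += cfg.reversal_strength
            scores[down_mask] -= cfg.reversal_strength
        cid = f"{role}_{i + 1:03d}"
        profiles.append(RankedProfile.from_scores(cid, dict(zip(gene_arr, scores))))
        records.append({"compound_id": cid, "role": role})
    return profiles, pd.DataFrame(records)


def _gompertz_sample(
    rng: np.random.Generator, n: int, shape: float, scale: float
) -> np.ndarray:
    """Inverse-CDF draw from the Gompertz law of mortality.

    Hazard h(t) = scale * exp(shape * t); survivor
    S(t) = exp(-(scale/shape) * (exp(shape*t) - 1)).
    """
    u = rng.uniform(size=n)
    return np.log1p(-(shape / scale) * np.log(u)) / shape


def gen_lifespans(cfg: SimConfig, paired: bool = False) -> pd.DataFrame:
    """Simulate control and treated mouse lifespan cohorts.

    Control durations follow Gompertz(``lifespan_shape``, ``lifespan_scale``);
    treated durations are Gompertz draws with the time axis multiplied by
    ``treatment_effect`` (accelerated-failure form), so the expected treated
    mean is exactly ``treatment_effect`` times the control mean. With
    ``paired=True`` the two groups reuse the same underlying uniform draws
    (common random numbers), which pins the *sample* mean ratio to the
    treatment effect — use this variance-reduced form for parameter-recovery
    checks, and the default independent form whenever the two groups must be
    statistically independent (e.g. test calibration). With
    ``censor_fraction > 0`` that fraction of each group is right-censored at
    a uniform time before death.

    Returns a tidy cohort table with columns ``subject_id``,
    ``duration_days``, ``event`` (1 = death observed) and ``group``.
    """
    if cfg.n_control < 1 or cfg.n_treated < 1:
        raise ValueError("cohort sizes must be >= 1")
    rng = _rng(cfg, _STREAM_LIFESPAN)
    control = _gompertz_sample(rng, cfg.n_control, cfg.lifespan_shape, cfg.lifespan_scale)
    if paired:
        treated = control[: cfg.n_treated].copy()
        if cfg.n_treated > cfg.n_control:
            extra = _gompertz_sample(
                rng, cfg.n_treated - cfg.n_control, cfg.lifespan_shape, cfg.lifespan_scale
            )
            treated = np.concatenate([treated, extra])
        treated = treated * cfg.treatment_effect
    else:
        treated = (
            _gompertz_sample(rng, cfg.n_treated, cfg.lifespan_shape, cfg.lifespan_scale)
            * cfg.treatment_effect
        )
    rows = []
    for group, durations in (("control", control), ("treated", treated)):
        n = len(durations)
        event = np.ones(n, dtype=int)
        if cfg.censor_fraction > 0:
            n_cens = int(round(cfg.censor_fraction * n))
            idx = rng.choice(n, size=n_cens, replace=False)
            event[idx] = 0
            durations = durations.copy()
            durations[idx] *= rng.uniform(0.0, 1.0, size=n_cens)
        for i, (d, e) in enumerate(zip(durations, event)):
            rows.append(
                {
                    "subject_id": f"{group}_{i + 1:03d}",
                    "duration_days": float(d),
                    "event": int(e),
                    "group": group,
                }
            )
    return pd.DataFrame(rows)


def _geometric_inverse_cdf(u: np.ndarray, p: float) -> np.ndarray:
    """Geometric (support 1, 2, ...) quantile transform of uniforms."""
    return np.maximum(1, np.ceil(np.log1p(-u) / math.log1p(-p))).astype(int)


def gen_budding_timelines(
    cfg: SimConfig,
    condition: str = "control",
    division_factor: float = 1.0,
    observation_window_h: float | None = None,
    paired: bool = False,
) -> list[BuddingTimeline]:
    """Simulate yeast mother-cell budding timelines.

    Each mother buds K times, K ~ geometric with mean
    ``mean_divisions * division_factor`` (memoryless per-division death);
    inter-bud durations are lognormal(``cycle_mu``, ``cycle_sigma``) hours.
    ``division_factor`` scales the expected replicative lifespan of this
    condition (1.0 = no effect; use e.g. 1.489 for a treated condition, or
    1.0 for a knockout that ignores the treatment). Conditions draw from
    independent streams keyed by their label; with ``paired=True`` the
    division counts instead come from a shared, condition-independent
    uniform stream through the geometric quantile transform, so two paired
    conditions differ only through ``division_factor`` (common random
    numbers — use for parameter-recovery checks, not for calibration). If
    ``observation_window_h`` is given, buds beyond the window are dropped
    and the mother is censored — mimicking a fixed imaging session.
    """
    if division_factor <= 0:
        raise ValueError("division_factor must be > 0")
    # distinct stream per condition label so conditions are independent;
    # crc32 is stable across processes (str hash is not)
    seed_tail = zlib.crc32(condition.encode()) % (2**31)
    rng = np.random.default_rng([int(cfg.seed), _STREAM_BUDDING, seed_tail])
    mean_div = cfg.mean_divisions * division_factor
    p = 1.0 / mean_div
    if paired:
        shared = np.random.default_rng([int(cfg.seed), _STREAM_BUDDING])
        u = shared.uniform(size=cfg.n_mothers)
    else:
        u = rng.uniform(size=cfg.n_mothers)
    ks = _geometric_inverse_cdf(u, p)
    timelines: list[BuddingTimeline] = []
    for i in range(cfg.n_mothers):
        k = int(ks[i])
        if cfg.cycle_sigma == 0:
            cycles = np.full(k, math.exp(cfg.cycle_mu))
        else:
            cycles = rng.lognormal(cfg.cycle_mu, cfg.cycle_sigma, size=k)
        times = np.cumsum(cycles)
        fate = "death"
        if observation_window_h is not None:
            kept = times[times <= observation_window_h]
            if len(kept) < len(times):
                fate = "censored"
            times = kept
        timelines.append(
            BuddingTimeline(
                mother_id=f"{condition}_m{i + 1:03d}",
                bud_times=tuple(times),
                fate=fate,
                condition=condition,
            )
        )
    return timelines
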