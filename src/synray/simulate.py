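"""Synthetic data generators with known ground truth.

Two families of inputs are emulated:

* plate-reader proliferation data — 4PL (Hill-type) responses in % of
  vehicle control with additive Gaussian noise, for single agents and for
  fixed-ratio mixtures whose interaction strength is set by an interaction
  index tau (tau = 1 exactly Loewe-additive, tau < 1 synergistic, tau > 1
  antagonistic: tau is the ground-truth Combination Index of the mixture at
  every effect level);

* microarray feature tables — multi-feature-per-gene treated/control ratio
  tables in triplicate, with planted consistent responders, optional
  contradictory features, Gaussian log2-ratio null noise, and error-model
  style P values produced by a deterministic monotone map from the log2
  ratio magnitude.

All randomness flows from the explicit ``seed`` carried by each parameter
object; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize

from .dose_response import DoseResponseData, four_pl
from .transcripts import ReplicateSet

__all__ = [
    "MonoGenParams",
    "ComboGenParams",
    "ArrayGenParams",
    "SimulatedArrays",
    "simulate_monotherapy",
    "simulate_combination",
    "simulate_feature_tables",
    "default_doses",
]


def default_doses(n: int = 8, low: float = 1.0, high: float = 100.0) -> np.ndarray:
    """Log-spaced dose ladder, μM (default 8 doses spanning 1-100)."""
    return np.geomspace(low, high, n)


@dataclass(frozen=True)
class MonoGenParams:
    """Ground truth for a single-agent proliferation simulation.

    Defaults mirror a 24 h WST-1 style screen: responses in % of vehicle
    control falling from 100 to 0, 8 log-spaced doses spanning 1-100 μM,
    6 replicate wells per dose, and 5% (of control) additive Gaussian noise.
    """

    ed50: float
    hillslope: float = -2.0
    bottom: float = 0.0
    top: float = 100.0
    noise_sd: float = 5.0
    doses: tuple = tuple(default_doses())
    n_replicates: int = 6
    seed: int = 0
    label: str = "simulated"

    def __post_init__(self):
        if not self.top > self.bottom:
            raise ValueError("top must exceed bottom")
        if not self.ed50 > 0:
            raise ValueError("ed50 must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_monotherapy(p: MonoGenParams) -> DoseResponseData:
    """Simulate replicate 4PL responses with additive Gaussian noise."""
    rng = np.random.default_rng(p.seed)
    doses = np.repeat(np.asarray(p.doses, float), p.n_replicates)
    clean = four_pl(doses, p.bottom, p.top, np.log10(p.ed50), p.hillslope)
    noise = rng.normal(0.0, p.noise_sd, size=doses.size) if p.noise_sd > 0 else 0.0
    reps = tuple(f"r{i + 1}" for _ in p.doses for i in range(p.n_replicates))
    return DoseResponseData(p.label, doses, clean + noise, reps)


@dataclass(frozen=True)
class ComboGenParams:
    """Ground truth for a fixed-ratio mixture on a tau-Loewe surface.

    At total dose Z with component doses (fraction_a*Z, fraction_b*Z), the
    noiseless percent effect x solves

        fraction_a*Z / Dx_a(x) + fraction_b*Z / Dx_b(x) = tau

    with Dx_* the exact inverse doses of the generating monotherapy curves,
    so the mixture's true Combination Index is tau at every effect level.

    The default total-dose ladder (8 log-spaced doses, 5-250 μM) brackets
    the Loewe-additive reference curve of the default monotherapy pair with
    margin on both sides, so mixtures with interaction indices between 0.25
    and 2 still traverse most of their dynamic range — the usual
    design-of-experiment requirement for a ray study.
    """

    params_a: MonoGenParams
    params_b: MonoGenParams
    fraction_a: float
    tau: float = 1.0
    total_doses: tuple = tuple(default_doses(8, 5.0, 250.0))
    noise_sd: float = 5.0
    n_replicates: int = 6
    seed: int = 0
    label: str = "simulated mixture"

    def __post_init__(self):
        if not 0.0 < self.fraction_a < 1.0:
            raise ValueError("fraction_a must be in (0, 1)")
        if not self.tau > 0:
            raise ValueError("tau must be > 0")

    @property
    def fraction_b(self) -> float:
        return 1.0 - self.fraction_a


def _true_inverse_dose(p: MonoGenParams, e: float) -> float:
    """Closed-form inverse of the generating 4PL at effect fraction e."""
    return 10.0 ** (np.log10(p.ed50) - np.log10(e / (1.0 - e)) / p.hillslope)


def noiseless_combination_response(p: ComboGenParams, total_dose: float) -> float:
    """Noiseless mixture response (% control) at one total dose.

    The mixture's response scale uses the mean of the two generating
    asymptote pairs (the same convention the additive construction uses).
    """
    top = 0.5 * (p.params_a.top + p.params_b.top)
    bottom = 0.5 * (p.params_a.bottom + p.params_b.bottom)
    if total_dose == 0:
        return top
    fa, fb = p.fraction_a, p.fraction_b

    def g(e):
        return (
            fa * total_dose / _true_inverse_dose(p.params_a, e)
            + fb * total_dose / _true_inverse_dose(p.params_b, e)
            - p.tau
        )

    lo, hi = 1e-12, 1.0 - 1e-12
    glo, ghi = g(lo), g(hi)
    if glo < 0:  # even a vanishing effect needs more than this dose
        warnings.warn("total dose below achievable effect range; clamping to top asymptote")
        return top
    if ghi > 0:
        warnings.warn("total dose beyond achievable effect range; clamping to bottom asymptote")
        return bottom
    e = optimize.brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16)
    return top - e * (top - bottom)


def simulate_combination(p: ComboGenParams) -> DoseResponseData:
    """Simulate fixed-ratio mixture responses on the tau-Loewe surface."""
    rng = np.random.default_rng(p.seed)
    totals = np.repeat(np.asarray(p.total_doses, float), p.n_replicates)
    clean = np.array([noiseless_combination_response(p, z) for z in totals])
    noise = rng.normal(0.0, p.noise_sd, size=totals.size) if p.noise_sd > 0 else 0.0
    reps = tuple(f"r{i + 1}" for _ in p.total_doses for i in range(p.n_replicates))
    return DoseResponseData(p.label, totals, clean + noise, reps)


def _default_p_model(abs_log2_ratio: np.ndarray) -> np.ndarray:
    """Deterministic monotone map from |log2 ratio| to an error-model-style P.

    Chosen so that a 2-fold change (|log2 ratio| = 1) maps to P = 1e-4,
    comfortably under the 0.01 cutoff, while typical null fluctuations
    (|log2 ratio| ~ 0.2) map to P ~ 0.16.
    """
    return np.clip(10.0 ** (-4.0 * np.asarray(abs_log2_ratio, float)), 1e-12, 1.0)


@dataclass(frozen=True)
class ArrayGenParams:
    """Ground truth for triplicate multi-feature-per-gene ratio tables.

    Parameters
    ----------
    n_genes : int
        Size of the gene universe (ids ``g0001``...).
    features_per_gene : (int, int)
        Inclusive range; each gene draws its feature count uniformly.
    planted : dict mapping treatment -> list of (gene_id, direction, magnitude)
        Responders planted consistently in all three replicates; direction
        is "up" or "down", magnitude is the fold change (>= 2).
    contradiction_rate : float in [0, 1]
        Probability that a planted gene (with >= 2 features) also receives
        one consistently opposing feature, making it contradictory.
    null_ratio_log2_sd : float
        SD of the Gaussian log2 ratio noise on unplanted features.
    p_model : callable
        Map from |log2 ratio| array to P values.
    """

    n_genes: int
    planted: dict
    features_per_gene: tuple[int, int] = (1, 3)
    contradiction_rate: float = 0.0
    null_ratio_log2_sd: float = 0.2
    p_model: Callable = field(default=_default_p_model)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.contradiction_rate <= 1.0:
            raise ValueError("contradiction_rate must be in [0, 1]")
        for treatment, plants in self.planted.items():
            for gene, direction, mag in plants:
                if mag < 2.0:
                    raise ValueError(
                        f"planted magnitude {mag} for {gene}/{treatment} is < 2"
                    )
                if direction not in ("up", "down"):
                    raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


@dataclass(frozen=True)
class SimulatedArrays:
    """Generated triplicate tables plus the ground-truth ledger.

    ``replicate_sets`` are the per-treatment triplicates over the shared
    feature universe (these double as the whole-array gene ratio lists:
    every feature is present with its ratio and P in every replicate).
    ``truth`` maps treatment -> sorted list of genes expected to survive
    filtering and gene resolution; ``contradicted`` lists planted genes
    spoiled by an opposing feature.
    """

    replicate_sets: dict
    truth: dict
    contradicted: dict

    @property
    def whole_array(self) -> dict:
        return {t: list(rs.replicates) for t, rs in self.replicate_sets.items()}


def simulate_feature_tables(p: ArrayGenParams) -> SimulatedArrays:
    """Generate triplicate feature tables with planted responders."""
    rng = np.random.default_rng(p.seed)
    genes = [f"g{i + 1:04d}" for i in range(p.n_genes)]
    lo, hi = p.features_per_gene
    n_feat = rng.integers(lo, hi + 1, size=p.n_genes)
    feature_gene = [
        (f"{g}_f{k + 1}", g) for g, nf in zip(genes, n_feat) for k in range(nf)
    ]
    feature_ids = [f for f, _ in feature_gene]
    gene_of = dict(feature_gene)
    first_feature = {}
    second_feature = {}
    for f, g in feature_gene:
        if g not in first_feature:
            first_feature[g] = f
        elif g not in second_feature:
            second_feature[g] = f

    replicate_sets = {}
    truth = {}
    contradicted = {}
    for treatment in sorted(p.planted):
        plants = p.planted[treatment]
        spoiled = []
        plan = {}  # feature_id -> (direction, magnitude)
        for gene, direction, mag in plants:
            if gene not in first_feature:
                raise ValueError(f"planted gene {gene} not in universe")
            plan[first_feature[gene]] = (direction, mag)
            if (
                p.contradiction_rate > 0
                and gene in second_feature
                and rng.random() < p.contradiction_rate
            ):
                opposite = "down" if direction == "up" else "up"
                plan[second_feature[gene]] = (opposite, mag)
                spoiled.append(gene)
        reps = []
        for _ in range(3):
            log2r = rng.normal(0.0, p.null_ratio_log2_sd, size=len(feature_ids))
            for i, f in enumerate(feature_ids):
                if f in plan:
                    direction, mag = plan[f]
                    jitter = 1.0 + abs(rng.normal(0.0, 0.05))
                    r = mag * jitter
                    log2r[i] = np.log2(r) if direction == "up" else -np.log2(r)
            ratio = 2.0**log2r
            pvals = p.p_model(np.abs(log2r))
            reps.append(
                pd.DataFrame(
                    {
                        "feature_id": feature_ids,
                        "gene_id": [gene_of[f] for f in feature_ids],
                        "ratio": ratio,
                        "p_value": pvals,
                    }
                )
            )
        replicate_sets[treatment] = ReplicateSet(treatment, tuple(reps))
        planted_genes = [g for g, _, _ in plants]
        truth[treatment] = sorted(set(planted_genes) - set(spoiled))
        contradicted[treatment] = sorted(spoiled)
    return SimulatedArrays(replicate_sets, truth, contradicted)
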