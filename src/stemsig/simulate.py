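"""Synthetic sorted-cell experiments and purity-mixed tumor cohorts.

Two generators with fully known ground truth:

* :func:`simulate_sorted_experiment` emulates a marker-sorting design —
  several cell lines, each split into marker-positive and marker-negative
  fractions, each fraction profiled in replicate. A set of planted genes is
  shifted up (or down) in the positive arms; a per-(gene, cell line) batch
  offset creates the cell-line heterogeneity that dominates real sorted-cell
  arrays.

* :func:`simulate_tumor_cohort` emulates a bulk tumor cohort in which each
  sample is an affine purity mixture of a tumor component and a
  stromal component.  Stemness activity lives only in the tumor component, so
  stemness and stromal signature scores become anticorrelated through purity
  even though the latent stemness activity is drawn independently of purity —
  the confounding mechanism that makes a hazardous stemness signature look
  protective in univariate survival analysis. Survival times follow a
  proportional-hazards model on the standardized latent activities.

All randomness flows from ``numpy.random.default_rng(seed)``; identical truth
objects yield bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CohortClinical, ExpressionMatrix

__all__ = [
    "SortedExperimentTruth",
    "CohortTruth",
    "simulate_sorted_experiment",
    "simulate_tumor_cohort",
]


# ---------------------------------------------------------------------------
# sorted-cell experiment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SortedExperimentTruth:
    """Design and ground truth of a simulated marker-sorting experiment.

    ``effect_size``, ``batch_sd`` and ``noise_sd`` are in standard-deviation
    units of the per-measurement noise. Values are gene-centered log
    expression (deviations from the per-gene platform average), so group
    means sit near zero and the SNR sd-floor, which scales with the group
    mean magnitude, behaves as it does on centered data.
    """

    planted_up: tuple[str, ...]
    planted_down: tuple[str, ...]
    n_genes: int = 2000
    effect_size: float = 3.0
    n_cell_lines: int = 3
    replicates_per_arm: int = 2
    batch_sd: float = 0.5
    noise_sd: float = 1.0
    baseline_mean: float = 0.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.planted_up) & set(self.planted_down):
            raise ValueError("planted up and down gene sets must be disjoint")
        if min(self.n_cell_lines, self.replicates_per_arm, self.n_genes) < 1:
            raise ValueError("counts must be >= 1")
        if min(self.batch_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be >= 0")

    @classmethod
    def default(
        cls,
        n_genes: int = 2000,
        n_up: int = 30,
        n_down: int = 30,
        seed: int = 0,
        **kwargs,
    ) -> "SortedExperimentTruth":
        """Truth with ``n_up``/``n_down`` planted genes named UP####/DN####."""
        up = tuple(f"UP{i:04d}" for i in range(n_up))
        down = tuple(f"DN{i:04d}" for i in range(n_down))
        return cls(planted_up=up, planted_down=down, n_genes=n_genes, seed=seed, **kwargs)

    @property
    def gene_ids(self) -> list[str]:
        n_bg = self.n_genes - len(self.planted_up) - len(self.planted_down)
        if n_bg < 0:
            raise ValueError("planted gene count exceeds total genes")
        return list(self.planted_up) + list(self.planted_down) + [
            f"BG{i:04d}" for i in range(n_bg)
        ]


def simulate_sorted_experiment(
    truth: SortedExperimentTruth,
) -> tuple[ExpressionMatrix, SortedExperimentTruth]:
    """Draw one sorted-cell experiment from ``truth``.

    value(g, s) = baseline(g) + batch(g, line(s)) + shift(g, status(s)) + noise,
    where shift is +effect_size for planted-up genes and −effect_size for
    planted-down genes in marker-positive arms, 0 otherwise.

    Sample annotations carry ``cell_line`` (CL1..) and ``cd133_status``
    (``pos``/``neg``).
    """
    genes = truth.gene_ids  # validates planted count
    rng = np.random.default_rng(truth.seed)
    n_genes = truth.n_genes
    lines = [f"CL{i + 1}" for i in range(truth.n_cell_lines)]

    baseline = rng.normal(truth.baseline_mean, truth.baseline_sd, size=n_genes)
    batch = rng.normal(0.0, truth.batch_sd, size=(n_genes, truth.n_cell_lines))

    shift = np.zeros(n_genes)
    shift[: len(truth.planted_up)] = truth.effect_size
    shift[len(truth.planted_up): len(truth.planted_up) + len(truth.planted_down)] = (
        -truth.effect_size
    )

    cols: dict[str, np.ndarray] = {}
    ann_rows = []
    for li, line in enumerate(lines):
        for status in ("pos", "neg"):
            for rep in range(1, truth.replicates_per_arm + 1):
                sid = f"{line}_{status}_r{rep}"
                noise = rng.normal(0.0, truth.noise_sd, size=n_genes)
                vals = baseline + batch[:, li] + noise
                if status == "pos":
                    vals = vals + shift
                cols[sid] = vals
                ann_rows.append({"sample_id": sid, "cell_line": line, "cd133_status": status})

    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    annotations = pd.DataFrame(ann_rows).set_index("sample_id")
    return ExpressionMatrix(values, annotations), truth


# ---------------------------------------------------------------------------
# purity-mixed tumor cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortTruth:
    """Configuration and (after simulation) realized truth of a tumor cohort.

    ``tumor_profile`` and ``stromal_profile`` are per-gene mean vectors over a
    shared gene universe; ``stemness_genes`` marks the genes whose tumor-
    component expression scales with the latent per-sample stemness activity,
    ``stromal_genes`` the genes elevated in the stromal component.

    The hazard is ``baseline_hazard * exp(beta_stemness * z(activity) +
    beta_stromal * z(1 - purity))`` with z the cohort z-score; betas are
    therefore log-hazard units per SD. ``purity`` and ``stemness_activity``
    are ``None`` on a configuration object and hold the realized per-sample
    vectors on the truth returned by :func:`simulate_tumor_cohort`.
    """

    tumor_profile: tuple[float, ...]
    stromal_profile: tuple[float, ...]
    gene_ids: tuple[str, ...]
    stemness_genes: tuple[str, ...]
    stromal_genes: tuple[str, ...]
    beta_stemness: float = 0.5
    beta_stromal: float = 1.5
    baseline_hazard: float = 0.1
    censor_rate: float = 0.3
    noise_sd: float = 0.5
    purity_alpha: float = 2.0
    purity_beta: float = 2.0
    subtype_log_odds_per_sd: float = 1.0
    seed: int = 0
    purity: tuple[float, ...] | None = None
    stemness_activity: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.tumor_profile) != len(self.stromal_profile) or len(
            self.tumor_profile
        ) != len(self.gene_ids):
            raise ValueError("tumor and stromal profiles must share the gene universe")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.purity is not None and (
            min(self.purity) < 0 or max(self.purity) > 1
        ):
            raise ValueError("purity must lie in [0, 1]")

    @classmethod
    def default(
        cls,
        n_genes: int = 2000,
        n_stemness: int = 100,
        n_stromal: int = 100,
        stemness_elevation: float = 2.0,
        stromal_elevation: float = 3.0,
        baseline_mean: float = 6.0,
        baseline_sd: float = 1.0,
        seed: int = 0,
        **kwargs,
    ) -> "CohortTruth":
        """Build profiles over a named gene universe.

        Stemness genes are elevated by ``stemness_elevation`` in the tumor
        component (so their bulk signal tracks purity as well as activity);
        stromal genes by ``stromal_elevation`` in the stromal component.
        """
        if n_stemness + n_stromal > n_genes:
            raise ValueError("marker genes exceed gene universe")
        stem = tuple(f"STEM{i:04d}" for i in range(n_stemness))
        strom = tuple(f"STROM{i:04d}" for i in range(n_stromal))
        bg = tuple(f"BG{i:04d}" for i in range(n_genes - n_stemness - n_stromal))
        genes = stem + strom + bg
        rng = np.random.default_rng(seed)
        base = rng.normal(baseline_mean, baseline_sd, size=n_genes)
        tumor = base.copy()
        stromal = base.copy()
        tumor[:n_stemness] += stemness_elevation
        stromal[n_stemness: n_stemness + n_stromal] += stromal_elevation
        return cls(
            tumor_profile=tuple(tumor),
            stromal_profile=tuple(stromal),
            gene_ids=genes,
            stemness_genes=stem,
            stromal_genes=strom,
            seed=seed,
            **kwargs,
        )

    @classmethod
    def for_universe(
        cls,
        gene_ids: Sequence[str],
        stemness_genes: Sequence[str],
        stromal_genes: Sequence[str],
        stemness_elevation: float = 2.0,
        stromal_elevation: float = 3.0,
        baseline_mean: float = 6.0,
        baseline_sd: float = 1.0,
        seed: int = 0,
        **kwargs,
    ) -> "CohortTruth":
        """Like :meth:`default` but over a caller-supplied gene universe,
        e.g. the genes of a sorted experiment whose derived signature is to
        be scored on the cohort."""
        gene_ids = tuple(gene_ids)
        stem = tuple(stemness_genes)
        strom = tuple(stromal_genes)
        unknown = (set(stem) | set(strom)) - set(gene_ids)
        if unknown:
            raise ValueError(f"marker genes outside the universe: {sorted(unknown)[:5]}")
        if set(stem) & set(strom):
            raise ValueError("stemness and stromal marker sets must be disjoint")
        rng = np.random.default_rng(seed)
        base = rng.normal(baseline_mean, baseline_sd, size=len(gene_ids))
        tumor = base.copy()
        stromal = base.copy()
        stem_mask = np.isin(np.array(gene_ids), stem)
        strom_mask = np.isin(np.array(gene_ids), strom)
        tumor[stem_mask] += stemness_elevation
        stromal[strom_mask] += stromal_elevation
        return cls(
            tumor_profile=tuple(tumor),
            stromal_profile=tuple(stromal),
            gene_ids=gene_ids,
            stemness_genes=stem,
            stromal_genes=strom,
            seed=seed,
            **kwargs,
        )


def _administrative_censor_times(
    times: np.ndarray, censor_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform(0, tau) entry censoring, tau solved so the expected censored
    fraction matches ``censor_rate`` for the realized event-time distribution."""
    if censor_rate == 0:
        return np.full_like(times, np.inf)

    def expected_censored(tau: float) -> float:
        # P(C < T) for C ~ U(0, tau): min(T, tau)/tau
        return float(np.mean(np.minimum(times, tau) / tau))

    lo, hi = 1e-9, float(times.max()) * 1e3
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected_censored(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    tau = 0.5 * (lo + hi)
    return rng.uniform(0.0, tau, size=len(times))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


def simulate_tumor_cohort(
    truth: CohortTruth, n_samples: int
) -> tuple[ExpressionMatrix, CohortClinical, CohortTruth]:
    """Draw a purity-mixed bulk cohort with survival outcomes.

    expression(g, i) = purity_i * (tumor_profile_g + activity_i * 1[g stem])
    + (1 - purity_i) * stromal_profile_g + noise. Survival times are
    exponential with the proportional hazard stated on :class:`CohortTruth`;
    censoring is administrative with Uniform(0, tau) entry.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(truth.seed)
    genes = np.array(truth.gene_ids)
    tumor = np.array(truth.tumor_profile)
    stromal = np.array(truth.stromal_profile)
    stem_ind = np.isin(genes, truth.stemness_genes).astype(float)

    purity = rng.beta(truth.purity_alpha, truth.purity_beta, size=n_samples)
    activity = rng.normal(0.0, 1.0, size=n_samples)

    noise = rng.normal(0.0, truth.noise_sd, size=(len(genes), n_samples))
    expr = (
        purity[None, :] * (tumor[:, None] + activity[None, :] * stem_ind[:, None])
        + (1.0 - purity)[None, :] * stromal[:, None]
        + noise
    )

    sample_ids = [f"T{i + 1:04d}" for i in range(n_samples)]
    values = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=sample_ids)

    # proportional hazards on the standardized latents
    z_act = _zscore(activity) if n_samples > 1 else np.zeros(1)
    z_strom = _zscore(1.0 - purity) if n_samples > 1 else np.zeros(1)
    hazard = truth.baseline_hazard * np.exp(
        truth.beta_stemness * z_act + truth.beta_stromal * z_strom
    )
    event_times = rng.exponential(1.0 / hazard)
    censor_times = _administrative_censor_times(event_times, truth.censor_rate, rng)
    event = (event_times <= censor_times).astype(int)
    time = np.minimum(event_times, censor_times)
    time = np.maximum(time, 1e-9)  # guard against a zero draw

    # 2-level subtype: log-odds of 'intestinal' = subtype_log_odds_per_sd * z(activity)
    p_intestinal = 1.0 / (1.0 + np.exp(-truth.subtype_log_odds_per_sd * z_act))
    subtype = np.where(rng.uniform(size=n_samples) < p_intestinal, "intestinal", "diffuse")

    clinical = CohortClinical(
        pd.DataFrame(
            {
                "purity": purity,
                "stemness_activity": activity,
                "subtype": subtype,
                "time": time,
                "event": event,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        time_col="time",
        event_col="event",
    )
    annotations = clinical.table.drop(columns=["time", "event"]).copy()
    matrix = ExpressionMatrix(values, annotations)
    realized = replace(
        truth, purity=tuple(purity), stemness_activity=tuple(activity)
    )
    return matrix, clinical, realized
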