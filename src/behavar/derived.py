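"""Derived quantities: variances, repeatability, contrasts, syndromes, BLUPs.

Every quantity is computed draw-wise from the posterior samples and only then
summarized (posterior mean + 95% highest posterior density interval).  Ratios
and exponentials do not commute with posterior expectations, so plugging
posterior means into the formulas gives slightly different numbers — the
draw-wise path is the reported one.

The expected residual ("within-individual") variance of a group combines the
dispersion fixed effects with the among-individual variance in log residual
SD: if log sigma_i ~ N(m, v) then E[sigma_i] = exp(m + v/2) and the reported
within-individual variance is (E[sigma_i])^2 = exp(2m + v).  Pool-level
dispersion variance is deliberately excluded from this quantity (metadata
records the choice).  Repeatability is V_among / (V_among + V_residual).

Group contrasts ("Delta Exposure") are exposed-minus-naive throughout; for
population-level rows the contrast is the predator coefficient itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .model import U_COMPONENTS
from .records import GROUPS, TRAITS

TRAIT_LABEL = {0: "distance_moved", 1: "time_to_emerge"}

#: named among-individual correlations: label -> (row, col) in the 6x6
#: correlation matrix over (intercept_dm, slope_dm, logsd_dm,
#: intercept_te, slope_te, logsd_te)
CORRELATION_LABELS = {
    "behavioral_syndrome": (0, 3),
    "plasticity_syndrome": (1, 4),
    "predictability_syndrome": (2, 5),
    "dm_personality_dm_plasticity": (0, 1),
    "te_personality_te_plasticity": (3, 4),
    "dm_personality_te_plasticity": (0, 4),
    "te_personality_dm_plasticity": (3, 1),
    "dm_personality_dm_predictability": (0, 2),
    "te_personality_te_predictability": (3, 5),
    "dm_personality_te_predictability": (0, 5),
    "te_personality_dm_predictability": (3, 2),
    "dm_plasticity_dm_predictability": (1, 2),
    "te_plasticity_te_predictability": (4, 5),
    "dm_plasticity_te_predictability": (1, 5),
    "te_plasticity_dm_predictability": (4, 2),
}


def expected_residual_variance(m, v):
    """Within-individual variance from the dispersion model.

    ``m`` is the log-residual-SD fixed part (group term included for the
    exposed group); ``v`` the among-individual variance of log residual SD.
    Returns (exp(m + v/2))^2 = exp(2m + v), applied elementwise.
    """
    m = np.asarray(m, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("variance of log residual SD must be non-negative")
    return np.exp(2.0 * m + v)


def repeatability(v_among, v_residual):
    """Proportion of phenotypic variance among individuals."""
    v_among = np.asarray(v_among, dtype=float)
    v_residual = np.asarray(v_residual, dtype=float)
    if np.any(v_among < 0) or np.any(v_residual < 0):
        raise ValueError("variance components must be non-negative")
    total = v_among + v_residual
    if np.any(total == 0):
        raise ValueError("repeatability undefined when both variances are zero")
    return v_among / total


def hpdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` draws."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 samples for an HPDI")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def group_difference(naive_draws, exposed_draws):
    """Draw-wise exposed-minus-naive contrast."""
    return np.asarray(exposed_draws, dtype=float) - np.asarray(naive_draws, dtype=float)


def significance_flag(mean: float, interval: tuple[float, float], kind: str) -> bool:
    """Reporting convention for 'significant' estimates.

    signed quantities: the 95% HPDI excludes 0.  variance quantities (which
    cannot be negative): the lower HPDI bound exceeds 0.01.
    """
    lo, hi = interval
    if lo > hi:
        raise ValueError("invalid interval")
    if kind == "signed":
        return bool(lo > 0.0 or hi < 0.0)
    if kind == "variance":
        return bool(lo > 0.01)
    raise ValueError("kind must be 'signed' or 'variance'")


def _summary_row(draws, kind: str, mass: float = 0.95) -> dict:
    draws = np.asarray(draws, dtype=float)
    lo, hi = hpdi(draws, mass)
    mean = float(np.mean(draws))
    return {
        "mean": mean,
        "lower": lo,
        "upper": hi,
        "significant": significance_flag(mean, (lo, hi), kind),
    }


@dataclass
class DerivedSummaries:
    """All report tables plus the underlying draw-wise quantities.

    ``table1`` population-level effects (initial behavior, plasticity to
    repeated testing, predictability), ``table2`` among-individual variances,
    within-individual variances and repeatability, ``table3`` among-individual
    correlations, ``table4`` covariate and pool effects.  ``quantities`` maps
    quantity names to their draw vectors for downstream computation.
    ``metadata`` records conventions (e.g. that pool-level dispersion variance
    is excluded from V_residual).
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    quantities: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def tables(self) -> dict:
        return {
            "table1": self.table1,
            "table2": self.table2,
            "table3": self.table3,
            "table4": self.table4,
        }

    def to_text(self) -> str:
        chunks = []
        titles = {
            "table1": "Population-level effects of predator exposure",
            "table2": "Among- and within-individual variances and repeatability",
            "table3": "Among-individual correlations",
            "table4": "Covariate and pool-of-origin effects",
        }
        for name, tab in self.tables().items():
            chunks.append(titles[name])
            chunks.append(tab.to_string(index=False, float_format=lambda x: f"{x: .3f}"))
            chunks.append("")
        return "\n".join(chunks)


def summarize(draws, mass: float = 0.95) -> DerivedSummaries:
    """Compute every reported quantity draw-wise from posterior samples."""
    beta = draws.stacked("beta")          # (S, 2, 10)
    delta = draws.stacked("delta")        # (S, 2, 2)
    sd_g = draws.stacked("sd_g")          # (S, 2, 6)
    corr_g = draws.stacked("corr_g")      # (S, 2, 6, 6)
    sd_pool = draws.stacked("sd_pool")    # (S, 4)

    q: dict[str, np.ndarray] = {}
    for k, trait in TRAIT_LABEL.items():
        q[f"initial_{trait}_naive"] = beta[:, k, 0]
        q[f"initial_{trait}_exposed"] = beta[:, k, 0] + beta[:, k, 1]
        q[f"initial_{trait}_delta"] = beta[:, k, 1]
        q[f"plasticity_{trait}_naive"] = beta[:, k, 2]
        q[f"plasticity_{trait}_exposed"] = beta[:, k, 2] + beta[:, k, 3]
        q[f"plasticity_{trait}_delta"] = beta[:, k, 3]
        q[f"predictability_{trait}_naive"] = delta[:, k, 0]
        q[f"predictability_{trait}_exposed"] = delta[:, k, 0] + delta[:, k, 1]
        q[f"predictability_{trait}_delta"] = delta[:, k, 1]
        for g, gname in enumerate(GROUPS):
            v_among = sd_g[:, g, 3 * k] ** 2
            v_plast = sd_g[:, g, 3 * k + 1] ** 2
            v_logsd = sd_g[:, g, 3 * k + 2] ** 2
            m = delta[:, k, 0] + delta[:, k, 1] * g
            v_resid = expected_residual_variance(m, v_logsd)
            q[f"v_among_{trait}_{gname}"] = v_among
            q[f"v_plasticity_{trait}_{gname}"] = v_plast
            q[f"v_predictability_{trait}_{gname}"] = v_logsd
            q[f"v_within_{trait}_{gname}"] = v_resid
            q[f"repeatability_{trait}_{gname}"] = repeatability(v_among, v_resid)
        for stem in ("v_among", "v_plasticity", "v_predictability", "v_within",
                     "repeatability"):
            q[f"{stem}_{trait}_delta"] = group_difference(
                q[f"{stem}_{trait}_naive"], q[f"{stem}_{trait}_exposed"]
            )

    for label, (i, j) in CORRELATION_LABELS.items():
        for g, gname in enumerate(GROUPS):
            q[f"corr_{label}_{gname}"] = corr_g[:, g, i, j]
        q[f"corr_{label}_delta"] = group_difference(
            q[f"corr_{label}_naive"], q[f"corr_{label}_exposed"]
        )

    # covariate effects and pool variances (table 4)
    covariate_terms = {
        "size": 4,
        "batch2": 5,
        "batch3": 6,
        "batch4": 7,
        "batch5": 8,
        "density": 9,
    }
    for k, trait in TRAIT_LABEL.items():
        for term, col in covariate_terms.items():
            q[f"fixed_{term}_{trait}"] = beta[:, k, col]
        q[f"v_pool_mean_{trait}"] = sd_pool[:, k] ** 2
        q[f"v_pool_disp_{trait}"] = sd_pool[:, 2 + k] ** 2

    # --- assemble tables --------------------------------------------------
    def rows_for(section, stem, kind_group, kind_delta):
        rows = []
        for k, trait in TRAIT_LABEL.items():
            for gname in (*GROUPS, "delta"):
                key = f"{stem}_{trait}_{gname}"
                kind = kind_delta if gname == "delta" else kind_group
                rows.append(
                    {
                        "section": section,
                        "trait": trait,
                        "group": "delta_exposure" if gname == "delta" else gname,
                        **_summary_row(q[key], kind, mass),
                    }
                )
        return rows

    table1 = pd.DataFrame(
        rows_for("initial_behavior", "initial", "signed", "signed")
        + rows_for("plasticity", "plasticity", "signed", "signed")
        + rows_for("predictability", "predictability", "signed", "signed")
    )
    table2 = pd.DataFrame(
        rows_for("v_among_initial", "v_among", "variance", "signed")
        + rows_for("v_among_plasticity", "v_plasticity", "variance", "signed")
        + rows_for("v_among_predictability", "v_predictability", "variance", "signed")
        + rows_for("v_within", "v_within", "variance", "signed")
        + rows_for("repeatability", "repeatability", "variance", "signed")
    )

    rows3 = []
    for label in CORRELATION_LABELS:
        for gname in (*GROUPS, "delta"):
            key = f"corr_{label}_{gname}"
            rows3.append(
                {
                    "correlation": label,
                    "group": "delta_exposure" if gname == "delta" else gname,
                    **_summary_row(q[key], "signed", mass),
                }
            )
    table3 = pd.DataFrame(rows3)

    rows4 = []
    for k, trait in TRAIT_LABEL.items():
        for term in covariate_terms:
            rows4.append(
                {
                    "section": "fixed_effect",
                    "term": term,
                    "trait": trait,
                    **_summary_row(q[f"fixed_{term}_{trait}"], "signed", mass),
                }
            )
        rows4.append(
            {
                "section": "pool_variance_mean_model",
                "term": "pool_of_origin",
                "trait": trait,
                **_summary_row(q[f"v_pool_mean_{trait}"], "variance", mass),
            }
        )
        rows4.append(
            {
                "section": "pool_variance_dispersion_model",
                "term": "pool_of_origin",
                "trait": trait,
                **_summary_row(q[f"v_pool_disp_{trait}"], "variance", mass),
            }
        )
    table4 = pd.DataFrame(rows4)

    return DerivedSummaries(
        table1=table1,
        table2=table2,
        table3=table3,
        table4=table4,
        quantities=q,
        metadata={
            "hpdi_mass": mass,
            "v_residual_includes_pool_dispersion": False,
            "delta_convention": "exposed_minus_naive",
        },
    )


def posterior_mode(samples: np.ndarray, bandwidth: str | float = "silverman",
                   grid_size: int = 512) -> float:
    """Mode of a sample via Gaussian KDE (Silverman bandwidth by default)."""
    x = np.asarray(samples, dtype=float).ravel()
    if np.all(x == x[0]):
        return float(x[0])
    kde = gaussian_kde(x, bw_method=bandwidth)
    lo, hi = x.min(), x.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    return float(grid[np.argmax(kde(grid))])


def blups(draws) -> pd.DataFrame:
    """Per-individual posterior mean and mode of each random-effect component.

    One row per individual; columns ``<component>_mean`` and
    ``<component>_mode`` for the 6 components plus the group label.
    """
    u = draws.stacked("u")  # (S, n_ind, 6)
    n_ind = u.shape[1]
    rows = []
    for i in range(n_ind):
        row = {
            "individual": draws.individuals[i] if draws.individuals else str(i),
            "group": GROUPS[draws.ind_group[i]] if len(draws.ind_group) else "",
        }
        for c, comp in enumerate(U_COMPONENTS):
            row[f"{comp}_mean"] = float(np.mean(u[:, i, c]))
            row[f"{comp}_mode"] = posterior_mode(u[:, i, c])
        rows.append(row)
    return pd.DataFrame(rows)
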