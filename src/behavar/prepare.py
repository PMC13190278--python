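"""Standardization and design encoding of raw assay records.

Distance moved is natural-log-transformed (strictly positive, multiplicative
errors) and z-scored; emergence time is z-scored untransformed.  Z-scoring
statistics are computed over observation rows with censored values included
at their bound, mirroring what a formula interface sees in the response
column.  The censoring bounds are pushed through the same affine maps so the
likelihood can evaluate tail probabilities on the standardized scale.  Size
and density are individual-level covariates and are centered/scaled over each
individual's unique value by default.

All scaling metadata is retained so every transform can be inverted exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import (
    CENSOR_CODE,
    GROUPS,
    TE_BOUNDS,
    TRAITS,
    check_columns,
)

N_BATCHES = 5


@dataclass
class TraitScaling:
    transform: str  # "log" or "identity"
    mean: float
    sd: float

    def forward(self, raw):
        x = np.log(raw) if self.transform == "log" else np.asarray(raw, dtype=float)
        return (x - self.mean) / self.sd

    def inverse(self, y):
        x = np.asarray(y, dtype=float) * self.sd + self.mean
        return np.exp(x) if self.transform == "log" else x


@dataclass
class CovariateScaling:
    size_mean: float
    size_sd: float
    density_mean: float
    density_sd: float
    scope: str = "individual"


@dataclass
class PreparedDataset:
    """Design-encoded dataset on the standardized scale.

    Observation arrays all have length ``n_obs``; ``X`` holds the 10 mean
    fixed-effect columns (see :data:`behavar.model.MEAN_TERMS`).
    """

    y: np.ndarray
    trait: np.ndarray
    censor: np.ndarray
    trial: np.ndarray
    group_obs: np.ndarray
    X: np.ndarray
    ind_idx: np.ndarray
    pool_idx: np.ndarray
    ind_group: np.ndarray
    ind_pool: np.ndarray
    pool_group: np.ndarray
    bounds: np.ndarray  # (2, 2): per trait (lower, upper), standardized
    trait_scaling: dict
    covariate_scaling: CovariateScaling
    individuals: list
    pools: list

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_ind(self) -> int:
        return len(self.individuals)

    @property
    def n_pool(self) -> int:
        return len(self.pools)

    def invert(self, trait: int, y_std):
        """Map standardized responses of a trait back to raw units."""
        return self.trait_scaling[TRAITS[trait]].inverse(y_std)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for a in (self.y, self.trait, self.censor, self.trial, self.X,
                  self.ind_idx, self.pool_idx, self.ind_group):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()[:16]

    def scaling_to_json(self) -> str:
        d = {
            "traits": {
                name: {"transform": s.transform, "mean": s.mean, "sd": s.sd}
                for name, s in self.trait_scaling.items()
            },
            "covariates": {
                "size_mean": self.covariate_scaling.size_mean,
                "size_sd": self.covariate_scaling.size_sd,
                "density_mean": self.covariate_scaling.density_mean,
                "density_sd": self.covariate_scaling.density_sd,
                "scope": self.covariate_scaling.scope,
            },
            "bounds_standardized": self.bounds.tolist(),
        }
        return json.dumps(d, indent=2)


@dataclass
class ValidationReport:
    """Structural problems found in a record table.

    ``incomplete_individuals`` is informational (the design is allowed to be
    unbalanced); everything else is a problem that should be fixed or
    acknowledged before fitting.
    """

    duplicates: list = field(default_factory=list)
    out_of_range_trials: list = field(default_factory=list)
    censor_inconsistencies: list = field(default_factory=list)
    nonpositive_distance: list = field(default_factory=list)
    multi_group_individuals: list = field(default_factory=list)
    multi_pool_individuals: list = field(default_factory=list)
    incomplete_individuals: list = field(default_factory=list)

    @property
    def problems(self) -> list:
        out = []
        for kind in (
            "duplicates",
            "out_of_range_trials",
            "censor_inconsistencies",
            "nonpositive_distance",
            "multi_group_individuals",
            "multi_pool_individuals",
        ):
            out.extend((kind, item) for item in getattr(self, kind))
        return out

    @property
    def ok(self) -> bool:
        return not self.problems

    @property
    def n_incomplete(self) -> int:
        return len(self.incomplete_individuals)

    def summary(self) -> str:
        lines = [f"{len(self.problems)} structural problem(s)"]
        for kind, item in self.problems:
            lines.append(f"  {kind}: {item}")
        lines.append(
            f"{self.n_incomplete} individual(s) with incomplete trial series"
        )
        return "\n".join(lines)


def validate(records: pd.DataFrame) -> ValidationReport:
    """Report structural problems; never raises."""
    check_columns(records)
    rep = ValidationReport()

    dup = records.duplicated(subset=["individual", "trial", "trait"], keep=False)
    if dup.any():
        keys = records.loc[dup, ["individual", "trial", "trait"]]
        rep.duplicates = sorted(set(map(tuple, keys.itertuples(index=False))))

    n_trials = int(records["trial"].max()) + 1 if len(records) else 0
    bad_trial = (records["trial"] < 0) | (records["trial"] >= max(n_trials, 1))
    rep.out_of_range_trials = records.index[bad_trial].tolist()

    te = records["trait"] == "time_to_emerge"
    at_upper = te & np.isclose(records["value_raw"], TE_BOUNDS[1])
    at_lower = te & np.isclose(records["value_raw"], TE_BOUNDS[0])
    flag = records["censored"]
    bad = (
        (at_upper & (flag == "none"))
        | (at_lower & (flag == "none"))
        | ((flag == "right") & ~at_upper)
        | ((flag == "left") & ~at_lower)
        | (~te & (flag != "none"))
    )
    rep.censor_inconsistencies = records.index[bad].tolist()

    dm = records["trait"] == "distance_moved"
    rep.nonpositive_distance = records.index[dm & (records["value_raw"] <= 0)].tolist()

    per_ind = records.groupby("individual")
    grp_counts = per_ind["group"].nunique()
    rep.multi_group_individuals = grp_counts.index[grp_counts > 1].tolist()
    pool_counts = per_ind["pool"].nunique()
    rep.multi_pool_individuals = pool_counts.index[pool_counts > 1].tolist()

    trials_per_ind = per_ind["trial"].nunique()
    rep.incomplete_individuals = trials_per_ind.index[
        trials_per_ind < n_trials
    ].tolist()
    return rep


def prepare(
    records: pd.DataFrame,
    *,
    log_offset: float | None = None,
    covariate_scope: str = "individual",
    te_bounds: tuple[float, float] = TE_BOUNDS,
) -> PreparedDataset:
    """Convert raw assay records into the model-ready standardized dataset.

    Parameters
    ----------
    log_offset
        Optional constant added to distance before the log transform.  Off by
        default: nonpositive distances abort with an error, since distance is
        a strictly positive measurement.
    covariate_scope
        "individual" (default) centers/scales size and density over each
        individual's unique value; "observation" uses observation rows.
    """
    check_columns(records)
    records = records.reset_index(drop=True)
    if len(records) == 0:
        return _empty_prepared()

    bad_group = set(records["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown group labels: {sorted(bad_group)}")
    bad_trait = set(records["trait"]) - set(TRAITS)
    if bad_trait:
        raise ValueError(f"unknown trait labels: {sorted(bad_trait)}")
    bad_batch = set(records["batch"]) - set(range(1, N_BATCHES + 1))
    if bad_batch:
        raise ValueError(f"unknown batch levels: {sorted(bad_batch)}")

    per_ind = records.groupby("individual")
    for col, what in (("group", "groups"), ("pool", "pools")):
        n = per_ind[col].nunique()
        bad = n.index[n > 1].tolist()
        if bad:
            raise ValueError(f"individuals mapped to multiple {what}: {bad}")

    dm_mask = records["trait"] == "distance_moved"
    dm_vals = records.loc[dm_mask, "value_raw"]
    if log_offset is None:
        nonpos = dm_vals.index[dm_vals <= 0].tolist()
        if nonpos:
            raise ValueError(
                "distance moved must be strictly positive; offending rows: "
                f"{nonpos} (pass log_offset to add a constant before the log)"
            )
        offset = 0.0
    else:
        offset = float(log_offset)

    trait_idx = records["trait"].map({t: i for i, t in enumerate(TRAITS)}).to_numpy()
    censor = records["censored"].map(CENSOR_CODE).to_numpy()

    # per-trait transform + z-scoring over observation rows (censored rows
    # included at their bound value, which is how they appear in value_raw)
    y = np.empty(len(records))
    scaling = {}
    bounds = np.full((2, 2), [-np.inf, np.inf], dtype=float)
    for k, name in enumerate(TRAITS):
        mask = trait_idx == k
        raw = records.loc[mask, "value_raw"].to_numpy(dtype=float)
        if name == "distance_moved":
            x = np.log(raw + offset)
            transform = "log"
        else:
            x = raw.copy()
            transform = "identity"
        m = float(np.mean(x)) if mask.any() else 0.0
        s = float(np.std(x, ddof=0)) if mask.any() else 1.0
        if s == 0.0:
            s = 1.0
        scaling[name] = TraitScaling(transform, m, s)
        y[mask] = (x - m) / s
        if name == "time_to_emerge":
            bounds[k] = [(te_bounds[0] - m) / s, (te_bounds[1] - m) / s]

    individuals = sorted(records["individual"].unique())
    ind_pos = {v: i for i, v in enumerate(individuals)}
    ind_idx = records["individual"].map(ind_pos).to_numpy()
    pools = sorted(records["pool"].unique())
    pool_pos = {v: i for i, v in enumerate(pools)}
    pool_idx = records["pool"].map(pool_pos).to_numpy()

    first = records.drop_duplicates("individual").set_index("individual")
    grp_code = {g: i for i, g in enumerate(GROUPS)}
    ind_group = np.array([grp_code[first.loc[v, "group"]] for v in individuals])
    ind_pool = np.array([pool_pos[first.loc[v, "pool"]] for v in individuals])
    pool_group = np.zeros(len(pools), dtype=int)
    pool_group[ind_pool] = ind_group  # pools are nested in groups

    group_obs = ind_group[ind_idx]

    # covariate scaling
    if covariate_scope == "individual":
        size_vals = first.loc[individuals, "size"].to_numpy(dtype=float)
        dens_vals = first.loc[individuals, "density"].to_numpy(dtype=float)
    elif covariate_scope == "observation":
        size_vals = records["size"].to_numpy(dtype=float)
        dens_vals = records["density"].to_numpy(dtype=float)
    else:
        raise ValueError("covariate_scope must be 'individual' or 'observation'")
    cov_scaling = CovariateScaling(
        size_mean=float(np.mean(size_vals)),
        size_sd=float(np.std(size_vals, ddof=0)) or 1.0,
        density_mean=float(np.mean(dens_vals)),
        density_sd=float(np.std(dens_vals, ddof=0)) or 1.0,
        scope=covariate_scope,
    )
    size_z = (records["size"].to_numpy(dtype=float) - cov_scaling.size_mean) / cov_scaling.size_sd
    dens_z = (
        records["density"].to_numpy(dtype=float) - cov_scaling.density_mean
    ) / cov_scaling.density_sd

    trial = records["trial"].to_numpy(dtype=float)
    g = group_obs.astype(float)
    batch = records["batch"].to_numpy(dtype=int)
    X = np.column_stack(
        [np.ones(len(records)), g, trial, g * trial, size_z]
        + [(batch == b).astype(float) for b in range(2, N_BATCHES + 1)]
        + [dens_z]
    )

    return PreparedDataset(
        y=y,
        trait=trait_idx,
        censor=censor,
        trial=trial,
        group_obs=group_obs,
        X=X,
        ind_idx=ind_idx,
        pool_idx=pool_idx,
        ind_group=ind_group,
        ind_pool=ind_pool,
        pool_group=pool_group,
        bounds=bounds,
        trait_scaling=scaling,
        covariate_scaling=cov_scaling,
        individuals=individuals,
        pools=pools,
    )


def _empty_prepared() -> PreparedDataset:
    from .model import N_MEAN_TERMS

    return PreparedDataset(
        y=np.empty(0),
        trait=np.empty(0, dtype=int),
        censor=np.empty(0, dtype=int),
        trial=np.empty(0),
        group_obs=np.empty(0, dtype=int),
        X=np.empty((0, N_MEAN_TERMS)),
        ind_idx=np.empty(0, dtype=int),
        pool_idx=np.empty(0, dtype=int),
        ind_group=np.empty(0, dtype=int),
        ind_pool=np.empty(0, dtype=int),
        pool_group=np.empty(0, dtype=int),
        bounds=np.array([[-np.inf, np.inf], [-np.inf, np.inf]]),
        trait_scaling={
            "distance_moved": TraitScaling("log", 0.0, 1.0),
            "time_to_emerge": TraitScaling("identity", 0.0, 1.0),
        },
        covariate_scaling=CovariateScaling(0.0, 1.0, 0.0, 1.0),
        individuals=[],
        pools=[],
    )
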