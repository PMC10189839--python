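"""WT-standardized classification, meta-classes, k-means signatures, embedding.

Every metric is standardized against the wild-type reference distribution
(z = (value - WT mean)/WT SD) and classified with a symmetric 1-sigma band:
values at least one WT SD above the mean are "high", at least one below are
"low", anything in between is "wt-like".  Ligand interaction energies are
classified jointly in the two nucleotide states into a 3x3 grid of
Stable/Neutral/Unstable labels; RMSD-to-reference metrics are split two-way
(closed vs deviated) per state.  Each (metric, state, non-neutral category)
becomes one binary "meta-class" column; k-means groups of variants are then
summarized by the meta-classes most occupied within each group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

THREE_WAY_LABELS = ("low", "wt-like", "high")
ENERGY_CATEGORIES = ("Stable", "Neutral", "Unstable")
#: the full 3x3 label space for the two-state interaction-energy scheme
NINE_GROUP_LABELS = tuple(itertools.product(ENERGY_CATEGORIES, ENERGY_CATEGORIES))
RMSD_LABELS = ("closed", "deviated")


@dataclass
class ScoreTable:
    """Variant x nucleotide-state metric matrix plus WT reference statistics.

    Attributes
    ----------
    values : DataFrame
        Rows indexed by a ``(variant, nucleotide)`` MultiIndex, one column
        per metric.
    wt_stats : DataFrame
        Rows indexed by ``(nucleotide, metric)``, columns ``mean``, ``sd``,
        ``median`` — the wild-type reference distribution each metric is
        standardized against.
    wt_id : str
        Row label of the wild-type variant (default ``"WT"``).
    """

    values: pd.DataFrame
    wt_stats: pd.DataFrame
    wt_id: str = "WT"

    def __post_init__(self) -> None:
        if not isinstance(self.values.index, pd.MultiIndex) or self.values.index.nlevels != 2:
            raise ValueError("values must be indexed by (variant, nucleotide)")
        for state in self.states:
            if (self.wt_id, state) not in self.values.index:
                raise ValueError(f"WT row missing for nucleotide state {state!r}")

    @property
    def states(self) -> list:
        return sorted(self.values.index.get_level_values(1).unique())

    @property
    def metrics(self) -> list:
        return list(self.values.columns)

    @property
    def variants(self) -> list:
        return list(self.values.index.get_level_values(0).unique())

    def state_frame(self, state: str) -> pd.DataFrame:
        """Metric matrix for one nucleotide state, indexed by variant."""
        return self.values.xs(state, level=1)

    def wt_stat(self, state: str, metric: str, stat: str) -> float:
        try:
            return float(self.wt_stats.loc[(state, metric), stat])
        except KeyError as exc:
            raise KeyError(f"no WT {stat} recorded for metric {metric!r} in state {state!r}") from exc

    def z_frame(self, state: str) -> pd.DataFrame:
        """All metrics standardized by the WT mean/SD for one state."""
        frame = self.state_frame(state)
        out = {}
        for metric in frame.columns:
            mu = self.wt_stat(state, metric, "mean")
            sd = self.wt_stat(state, metric, "sd")
            if sd <= 0:
                raise ValueError(f"WT SD for metric {metric!r} in {state} is not positive")
            out[metric] = (frame[metric] - mu) / sd
        return pd.DataFrame(out, index=frame.index)

    def to_csv(self, values_path: str, wt_stats_path: str) -> None:
        self.values.to_csv(values_path)
        self.wt_stats.to_csv(wt_stats_path)

    @classmethod
    def from_csv(cls, values_path: str, wt_stats_path: str, wt_id: str = "WT") -> "ScoreTable":
        values = pd.read_csv(values_path, index_col=[0, 1])
        wt_stats = pd.read_csv(wt_stats_path, index_col=[0, 1])
        return cls(values=values, wt_stats=wt_stats, wt_id=wt_id)


def three_way_classify(value: float, wt_mean: float, wt_sd: float, threshold: float = 1.0) -> str:
    """Classify a metric value as low / wt-like / high against WT statistics.

    Boundaries are inclusive toward the extreme categories: a value exactly
    ``threshold`` WT SDs above the mean is "high", exactly ``threshold``
    below is "low".
    """
    if wt_sd <= 0:
        raise ValueError("WT SD must be positive")
    z = (value - wt_mean) / wt_sd
    if z >= threshold:
        return "high"
    if z <= -threshold:
        return "low"
    return "wt-like"


def _energy_category(z: float, threshold: float) -> str:
    # more-negative interaction energy = tighter nucleotide binding = Stable
    if z <= -threshold:
        return "Stable"
    if z >= threshold:
        return "Unstable"
    return "Neutral"


def energy_nine_group(gdp_z: float, gtp_z: float, threshold: float = 1.0) -> tuple:
    """Joint two-state interaction-energy category, one of 9 labels.

    Each state's WT-standardized mean interaction energy is categorized
    Stable (<= -threshold sigma), Neutral (within the band) or Unstable
    (>= +threshold sigma); the pair ``(GDP category, GTP category)`` spans a
    3x3 label space.
    """
    return (_energy_category(float(gdp_z), threshold), _energy_category(float(gtp_z), threshold))


def rmsd_two_way(value: float, wt_mean: float, wt_sd: float, threshold: float = 1.0) -> str:
    """Two-way split of an RMSD summary: WT-like ("closed") vs "deviated"."""
    if wt_sd <= 0:
        raise ValueError("WT SD must be positive")
    z = (value - wt_mean) / wt_sd
    return "deviated" if abs(z) >= threshold else "closed"


def rmsd_combined_label(metric: str, gtp_cat: str, gdp_cat: str) -> str:
    """Combined per-reference label, e.g. ``"RMSD NF1 GTP Closed GDP Deviated"``."""
    return f"{metric} GTP {gtp_cat.capitalize()} GDP {gdp_cat.capitalize()}"


@dataclass(frozen=True)
class ClassifierConfig:
    """Which metrics are classified by which scheme.

    ``three_way`` metrics yield "<metric> Above <state>" / "<metric> Below
    <state>" columns; ``fraction`` metrics (well-occupancy ratios) use the
    "Plus SD"/"Minus SD" wording instead; ``energy`` names the interaction-
    energy metric classified jointly across states into the 9-group scheme;
    ``rmsd_pairs`` metrics get the four combined closed/deviated columns.
    """

    three_way: tuple = ()
    fraction: tuple = ()
    energy: str | None = None
    rmsd_pairs: tuple = ()
    threshold: float = 1.0

    def column_names(self, states) -> list:
        """Deterministic meta-class column list for the given states."""
        cols = []
        for metric in self.three_way:
            for state in states:
                cols.append(f"{metric} Above {state}")
                cols.append(f"{metric} Below {state}")
        for metric in self.fraction:
            for state in states:
                cols.append(f"{metric} Plus SD {state}")
                cols.append(f"{metric} Minus SD {state}")
        if self.energy is not None:
            for gdp_cat, gtp_cat in NINE_GROUP_LABELS:
                cols.append(f"{self.energy} GDP {gdp_cat} GTP {gtp_cat}")
        for metric in self.rmsd_pairs:
            for gtp_cat in RMSD_LABELS:
                for gdp_cat in RMSD_LABELS:
                    cols.append(rmsd_combined_label(metric, gtp_cat, gdp_cat))
        return cols


def build_metaclass_matrix(table: ScoreTable, config: ClassifierConfig) -> pd.DataFrame:
    """Binary variant x meta-class membership matrix.

    One column per (metric, state, non-wt-like category) for three-way and
    fraction metrics, the full 9-label grid for the energy metric, and the
    four combined closed/deviated columns per RMSD metric.  The column set
    is a deterministic function of the config; columns a dataset never
    populates stay all-zero rather than being dropped.
    """
    states = table.states
    variants = table.variants
    columns = config.column_names(states)
    mat = pd.DataFrame(0, index=pd.Index(variants, name="variant"), columns=columns, dtype=int)
    thr = config.threshold

    for metric in list(config.three_way) + list(config.fraction):
        wording = ("Above", "Below") if metric in config.three_way else ("Plus SD", "Minus SD")
        for state in states:
            frame = table.state_frame(state)
            if metric not in frame.columns:
                raise KeyError(f"metric {metric!r} missing from score table")
            mu = table.wt_stat(state, metric, "mean")
            sd = table.wt_stat(state, metric, "sd")
            for variant in variants:
                cat = three_way_classify(frame.loc[variant, metric], mu, sd, thr)
                if cat == "high":
                    mat.loc[variant, f"{metric} {wording[0]} {state}"] = 1
                elif cat == "low":
                    mat.loc[variant, f"{metric} {wording[1]} {state}"] = 1

    if config.energy is not None:
        metric = config.energy
        if not {"GDP", "GTP"}.issubset(states):
            raise ValueError("energy 9-group scheme requires both GDP and GTP states")
        z_gdp = (
            table.state_frame("GDP")[metric] - table.wt_stat("GDP", metric, "mean")
        ) / table.wt_stat("GDP", metric, "sd")
        z_gtp = (
            table.state_frame("GTP")[metric] - table.wt_stat("GTP", metric, "mean")
        ) / table.wt_stat("GTP", metric, "sd")
        for variant in variants:
            gdp_cat, gtp_cat = energy_nine_group(z_gdp[variant], z_gtp[variant], thr)
            mat.loc[variant, f"{metric} GDP {gdp_cat} GTP {gtp_cat}"] = 1

    for metric in config.rmsd_pairs:
        if not {"GDP", "GTP"}.issubset(states):
            raise ValueError("RMSD combined labels require both GDP and GTP states")
        for variant in variants:
            cats = {}
            for state in ("GTP", "GDP"):
                value = table.state_frame(state).loc[variant, metric]
                mu = table.wt_stat(state, metric, "mean")
                sd = table.wt_stat(state, metric, "sd")
                cats[state] = rmsd_two_way(value, mu, sd, thr)
            mat.loc[variant, rmsd_combined_label(metric, cats["GTP"], cats["GDP"])] = 1

    return mat


def kmeans_groups(
    frame: pd.DataFrame,
    k: int = 6,
    seed: int = 0,
    n_restarts: int = 50,
    standardize: bool = True,
) -> pd.Series:
    """k-means group assignment of variants from one state's metric matrix.

    Columns are z-standardized (constant columns dropped) before clustering;
    the best of ``n_restarts`` seeded initializations by inertia is kept.
    """
    from sklearn.cluster import KMeans

    if k < 1:
        raise ValueError("k must be >= 1")
    if len(frame) < k:
        raise ValueError(f"k={k} exceeds the number of rows ({len(frame)})")
    x = frame.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=0)
        keep = sd > 0
        x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(x)
    return pd.Series(labels, index=frame.index, name="group")


@dataclass
class GroupSignature:
    """Ranked meta-classes most occupied within one k-means group."""

    group_id: int
    members: list
    ranked: list = field(default_factory=list)  # [(meta_class, occupancy fraction), ...]

    def top(self, n: int) -> list:
        return self.ranked[:n]


def group_signatures(
    groups: pd.Series,
    matrix: pd.DataFrame,
    top_n: int = 10,
) -> tuple[list, list]:
    """Per-group meta-class signatures plus the union of top-``top_n`` classes.

    Within each group every meta-class gets an occupancy fraction (share of
    members carrying it); classes are ranked by occupancy, ties broken by
    global occupancy across all variants, then by name.  The retained set is
    the union of each group's top ``top_n`` classes with nonzero occupancy —
    meta-classes defining no group are filtered out.
    """
    missing = [v for v in groups.index if v not in matrix.index]
    if missing:
        raise ValueError(f"variants missing from meta-class matrix: {missing}")
    global_occ = matrix.mean(axis=0)
    signatures = []
    retained: set = set()
    for gid in sorted(groups.unique()):
        members = list(groups.index[groups == gid])
        if not members:
            raise ValueError(f"group {gid} is empty")
        occ = matrix.loc[members].mean(axis=0)
        order = sorted(occ.index, key=lambda c: (-occ[c], -global_occ[c], c))
        ranked = [(c, float(occ[c])) for c in order]
        signatures.append(GroupSignature(group_id=int(gid), members=members, ranked=ranked))
        retained.update(c for c, o in ranked[:top_n] if o > 0)
    return signatures, sorted(retained)


def cross_correlation(table: ScoreTable, state: str) -> pd.DataFrame:
    """Pearson metric-by-metric correlation across variants for one state.

    Constant metrics produce NaN rows/columns, flagging the undefined
    correlations rather than silently dropping them.
    """
    frame = table.state_frame(state)
    if len(frame) < 3:
        raise ValueError("cross-correlation requires at least 3 variants")
    return frame.corr(method="pearson")


def embed_2d(
    frame: pd.DataFrame,
    method: str = "auto",
    seed: int = 0,
    missing: str = "drop",
    n_neighbors: int = 15,
) -> pd.DataFrame:
    """2D embedding of a per-(variant, state) metric matrix.

    ``method`` is ``"umap"`` (nonlinear neighbor embedding), ``"pca"``
    (always available, exactly distance-preserving on rank-2 data) or
    ``"auto"`` (UMAP when importable, else PCA).  Missing values are handled
    by dropping affected columns (default) or mean imputation.
    """
    if missing == "drop":
        frame = frame.dropna(axis=1)
    elif missing == "impute":
        frame = frame.fillna(frame.mean())
    else:
        raise ValueError("missing must be 'drop' or 'impute'")
    if frame.isna().to_numpy().any():
        raise ValueError("missing values remain after imputation policy")
    x = frame.to_numpy(dtype=float)

    if method == "auto":
        try:
            import umap  # noqa: F401

            method = "umap"
        except ImportError:
            method = "pca"

    if method == "umap":
        try:
            import umap
        except ImportError as exc:
            raise ValueError("umap-learn is not installed; use method='pca'") from exc
        nn = min(n_neighbors, max(2, len(frame) - 1))
        emb = umap.UMAP(n_components=2, n_neighbors=nn, random_state=seed).fit_transform(x)
    elif method == "pca":
        from sklearn.decomposition import PCA

        emb = PCA(n_components=2, random_state=seed).fit_transform(x)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(emb, index=frame.index, columns=["e1", "e2"])
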