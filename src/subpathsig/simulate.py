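"""Multi-cohort synthetic data with a planted protective subpathway.

The generator emulates the structure the discovery pipeline assumes: several
independent patient cohorts of log-scale expression sharing one gene
universe; one *planted* subpathway whose member genes load on a per-sample
latent factor, so the set's rank-contrast activity tracks that factor;
survival times drawn from an exponential proportional-hazards model whose
linear predictor is ``planted_log_hr`` per standard deviation of the planted
set's normalised activity (negative = protective); a cell-line panel whose
IC50 values are rank-correlated with planted activity inside the "classical"
subtype; and ordinal chemotherapy-response labels driven by activity.

Defaults mirror the study design the pipeline targets: 7 training plus 4
test cohorts of 500 patients, a protective effect of log HR = -0.5, two
RNA-seq-flavoured cohorts among the test sets, and a target IC50 rank
correlation of -0.5 among classical cell lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .activity import score_matrix
from .datatypes import Cohort, ConfigError, FeatureSet, MICROARRAY, PATHWAY, RNASEQ, SUBPATHWAY
from .pathways import PathwayGraph

PLANTED_PATHWAY = "path:90001"
PLANTED_SUBPATHWAY = "path:90001_1"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; identical config + seed => identical data.

    ``planted_log_hr`` is the hazard-ratio effect per 1 SD of normalised
    planted-set activity; ``ic50_rho`` the target Spearman correlation of
    IC50 vs activity within classical cell lines; ``censor_rate`` the
    expected fraction of censored patients.
    """

    n_cohorts: int = 11
    n_training: int = 7
    samples_per_cohort: int = 500
    n_genes: int = 2000
    planted_set_size: int = 10
    planted_log_hr: float = -0.5
    baseline_hazard: float = 0.1
    censor_rate: float = 0.3
    classical_fraction: float = 0.45
    ic50_rho: float = -0.5
    noise_sd: float = 1.0
    seed: int = 0
    # secondary structure
    n_decoy_pathways: int = 99
    chain_len: int = 4
    cohort_shift_sd: float = 0.2
    n_rnaseq_cohorts: int = 2
    n_cell_lines: int = 60
    n_drugs: int = 4
    planted_loading: float = 1.0

    def __post_init__(self) -> None:
        checks = [
            ("n_cohorts", self.n_cohorts >= 1),
            ("n_training", 1 <= self.n_training <= self.n_cohorts),
            ("samples_per_cohort", self.samples_per_cohort >= 4),
            ("n_genes", self.n_genes >= 2),
            ("planted_set_size", 1 <= self.planted_set_size < self.n_genes),
            ("baseline_hazard", self.baseline_hazard > 0),
            ("censor_rate", 0.0 <= self.censor_rate < 1.0),
            ("classical_fraction", 0.0 <= self.classical_fraction <= 1.0),
            ("ic50_rho", -1.0 <= self.ic50_rho <= 1.0),
            ("noise_sd", self.noise_sd > 0),
            ("n_decoy_pathways", self.n_decoy_pathways >= 0),
            ("chain_len", self.chain_len >= 2),
            ("n_rnaseq_cohorts", 0 <= self.n_rnaseq_cohorts <= self.n_cohorts),
            ("n_cell_lines", self.n_cell_lines >= 8),
            ("n_drugs", self.n_drugs >= 2),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigError(f"invalid configuration field: {name}")


@dataclass
class SyntheticCohortBundle:
    """Everything the pipeline consumes, generated from one config."""

    config: SimulationConfig
    cohorts: list[Cohort]
    feature_sets: list[FeatureSet]
    pathway_graphs: list[PathwayGraph]
    drug_table: pd.DataFrame  # cell_line, subtype, activity, one column per drug (IC50)
    response_table: pd.DataFrame  # sample, cohort, response in {CR,PR,SD,PD}
    latent: dict[str, pd.Series] = field(default_factory=dict)

    @property
    def training_cohorts(self) -> list[Cohort]:
        return self.cohorts[: self.config.n_training]

    @property
    def test_cohorts(self) -> list[Cohort]:
        return self.cohorts[self.config.n_training :]

    @property
    def planted_set(self) -> FeatureSet:
        return next(f for f in self.feature_sets if f.id == PLANTED_SUBPATHWAY)


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(1, n + 1)]


def _build_pathway(pid: str, clique_genes: list[str], chain_genes: list[str]) -> PathwayGraph:
    """Clique component (the informative/decoy subpathway) plus a separate
    chain component of auxiliary genes; disconnected, so distance-rule mining
    returns the clique and the chain as the pathway's two subpathways."""
    edges = [(a, b) for i, a in enumerate(clique_genes) for b in clique_genes[i + 1 :]]
    edges += list(zip(chain_genes[:-1], chain_genes[1:]))
    return PathwayGraph(pid, edges, nodes=clique_genes + chain_genes)


def _censor_scale(lam: np.ndarray, censor_rate: float) -> float:
    """Rate c of an independent exponential censor such that the expected
    censored fraction E[c / (c + lambda_i)] equals censor_rate."""
    if censor_rate == 0:
        return 0.0
    f = lambda c: np.mean(c / (c + lam)) - censor_rate
    hi = lam.max() * 1e4
    return float(brentq(f, 1e-12, hi))


def _spearman_to_pearson(rho_s: float) -> float:
    # bivariate-normal copula relation
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def generate_cohorts(config: SimulationConfig) -> SyntheticCohortBundle:
    """Draw a full synthetic study from one config (bit-reproducible).

    See the module docstring for the generative model.  Expression is
    i.i.d. normal per gene on the log2 scale around gene-specific means, with
    a cohort-level mean shift (inter-study heterogeneity) and the latent
    factor added to planted-set genes.  RNA-seq-flavoured cohorts (the last
    ``n_rnaseq_cohorts``) are exponentiated and rounded to counts, with the
    platform tag recorded.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)

    # --- feature sets and pathway graphs -------------------------------
    planted_genes = list(rng.choice(genes, size=cfg.planted_set_size, replace=False))
    remaining = [g for g in genes if g not in set(planted_genes)]
    feature_sets: list[FeatureSet] = []
    graphs: list[PathwayGraph] = []

    def add_pathway(pid: str, clique: list[str], pool: list[str]) -> None:
        pool = [g for g in pool if g not in set(clique)]
        chain = list(rng.choice(pool, size=min(cfg.chain_len, len(pool)), replace=False))
        g = _build_pathway(pid, clique, chain)
        graphs.append(g)
        feature_sets.append(
            FeatureSet(id=f"{pid}_1", level=SUBPATHWAY, genes=frozenset(clique), parent=pid)
        )
        feature_sets.append(
            FeatureSet(id=f"{pid}_2", level=SUBPATHWAY, genes=frozenset(chain), parent=pid)
        )
        feature_sets.append(
            FeatureSet(id=pid, level=PATHWAY, genes=frozenset(clique) | frozenset(chain), parent="")
        )

    add_pathway(PLANTED_PATHWAY, planted_genes, remaining)
    for j in range(cfg.n_decoy_pathways):
        size = int(rng.integers(max(4, cfg.planted_set_size - 3), cfg.planted_set_size + 4))
        size = min(size, len(remaining))
        clique = list(rng.choice(remaining, size=size, replace=False))
        add_pathway(f"path:9{1002 + j:04d}", clique, remaining)

    gene_means = rng.normal(7.0, 1.0, size=cfg.n_genes)
    planted_idx = np.array([genes.index(g) for g in planted_genes])

    # --- cohorts ---------------------------------------------------------
    cohorts: list[Cohort] = []
    latent: dict[str, pd.Series] = {}
    response_rows = []
    n_micro = cfg.n_cohorts - cfg.n_rnaseq_cohorts
    for c in range(cfg.n_cohorts):
        name = f"cohort{c + 1:02d}"
        platform = MICROARRAY if c < n_micro else RNASEQ
        ns = cfg.samples_per_cohort
        samples = [f"{name}_s{i:03d}" for i in range(1, ns + 1)]
        shift = rng.normal(0.0, cfg.cohort_shift_sd)
        z = rng.normal(0.0, 1.0, size=ns)
        expr = gene_means[:, None] + shift + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, ns))
        expr[planted_idx] += cfg.planted_loading * z[None, :]
        log_expr = pd.DataFrame(
            expr, index=pd.Index(genes, name="gene_id"), columns=samples
        )

        # hazard driven by the planted set's normalised rank-contrast activity
        act = score_matrix(log_expr, [feature_sets[0]])  # planted subpathway only
        a_norm = act.normalized.iloc[0].to_numpy()
        lam = cfg.baseline_hazard * np.exp(cfg.planted_log_hr * a_norm)
        t_event = rng.exponential(1.0 / lam)
        c_rate = _censor_scale(lam, cfg.censor_rate)
        if c_rate > 0:
            t_cens = rng.exponential(1.0 / c_rate, size=ns)
        else:
            t_cens = np.full(ns, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        time = np.maximum(time, 1e-9)

        subtype = np.where(
            rng.random(ns) < cfg.classical_fraction, "classical", "basal"
        )
        surv = pd.DataFrame(
            {
                "time": time,
                "event": event,
                "age": np.round(rng.normal(65.0, 10.0, size=ns), 1),
                "sex": rng.choice(["female", "male"], size=ns),
                "subtype": subtype,
            },
            index=pd.Index(samples, name="sample_id"),
        )

        values = log_expr
        if platform == RNASEQ:
            values = np.round(np.exp2(log_expr)).astype(float)
        cohorts.append(Cohort(name=name, expression=values, survival=surv, platform=platform))
        latent[name] = pd.Series(z, index=samples)

        if c == cfg.n_cohorts - 1:
            # ordinal response labels for the last cohort: noisy monotone in activity
            score = a_norm + rng.normal(0.0, 0.8, size=ns)
            qs = np.quantile(score, [0.30, 0.65, 0.85])
            lab = np.select(
                [score < qs[0], score < qs[1], score < qs[2]], ["PD", "SD", "PR"], "CR"
            )
            for s, l in zip(samples, lab):
                response_rows.append({"sample_id": s, "cohort": name, "response": l})

    # --- cell-line panel -------------------------------------------------
    n_cl = cfg.n_cell_lines
    lines = [f"cell{j:03d}" for j in range(1, n_cl + 1)]
    z_cl = rng.normal(0.0, 1.0, size=n_cl)
    expr_cl = gene_means[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_cl))
    expr_cl[planted_idx] += cfg.planted_loading * z_cl[None, :]
    act_cl = score_matrix(
        pd.DataFrame(expr_cl, index=genes, columns=lines), [feature_sets[0]]
    ).normalized.iloc[0]
    classical = rng.random(n_cl) < cfg.classical_fraction
    # guarantee a usable subset on both sides
    while classical.sum() < 4:
        classical[int(rng.integers(n_cl))] = True
    while (~classical).sum() < 1:
        classical[int(rng.integers(n_cl))] = False

    rho_p = _spearman_to_pearson(cfg.ic50_rho)
    a_vals = act_cl.to_numpy()
    # normal scores of activity within the classical subset (gaussian copula)
    from scipy.stats import norm, rankdata

    drug_cols = {}
    for d in range(cfg.n_drugs):
        latent_ic = rng.normal(0.0, 1.0, size=n_cl)
        cl = np.where(classical)[0]
        ranks = rankdata(a_vals[cl], method="average")
        zscores = norm.ppf((ranks - 0.5) / cl.size)
        eps = rng.normal(0.0, 1.0, size=cl.size)
        latent_ic[cl] = rho_p * zscores + np.sqrt(max(0.0, 1.0 - rho_p**2)) * eps
        drug_cols[f"drug{d + 1}"] = np.exp(latent_ic)  # positive, log-normal IC50

    drug_table = pd.DataFrame(
        {
            "subtype": np.where(classical, "classical", "basal"),
            "activity": a_vals,
            **drug_cols,
        },
        index=pd.Index(lines, name="cell_line"),
    )
    response_table = pd.DataFrame(response_rows).set_index("sample_id")

    return SyntheticCohortBundle(
        config=cfg,
        cohorts=cohorts,
        feature_sets=feature_sets,
        pathway_graphs=graphs,
        drug_table=drug_table,
        response_table=response_table,
        latent=latent,
    )
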