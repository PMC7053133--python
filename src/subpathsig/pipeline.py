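"""End-to-end orchestration: discovery on training cohorts, validation by
meta-analysis and drug-response association.

``run_discovery`` executes the full selection procedure (activity scoring,
per-cohort Cox screening, ipScore over cohort combinations, top-30 ranking,
frequency selection, serial-set assessment on test cohorts) and
``run_validation`` pools a chosen signature's per-cohort hazard ratios
(fixed/random auto-selection, platform subgroups, leave-one-out sensitivity,
funnel data) and tests its drug-sensitivity and response associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import discovery, drugs, meta
from .activity import ActivityMatrix, score_matrix
from .datatypes import Cohort, DataError, FeatureSet, GENE, MetaResult, StudyEstimate
from .survival import cox_univariate_table


@dataclass
class DiscoveryResult:
    """All intermediate and final tables of one discovery run."""

    pvalues: dict[str, pd.DataFrame]  # level -> features x training cohorts
    ipscores: dict[str, pd.DataFrame]  # level -> features x combinations
    top_lists: dict[str, dict[str, list[str]]]  # level -> combination -> top-30 ids
    frequency: dict[str, pd.DataFrame]  # level -> frequency report
    selected: dict[str, list[str]]  # level -> candidate ids
    serial_assessment: pd.DataFrame | None = None
    activities: dict[str, ActivityMatrix] = field(default_factory=dict)


def gene_level_features(genes, n: int | None = None) -> list[FeatureSet]:
    ids = list(genes)[: n or len(list(genes))]
    return [FeatureSet(id=g, level=GENE, genes=frozenset([g])) for g in ids]


def _screen_level(
    cohorts: list[Cohort],
    features: list[FeatureSet],
    sign: int,
    activities: dict[str, ActivityMatrix],
    cache_key: str,
) -> pd.DataFrame:
    cols = {}
    for cohort in cohorts:
        am = score_matrix(cohort.expression, features, sign=sign)
        activities[f"{cache_key}:{cohort.name}"] = am
        cols[cohort.name] = discovery.screen_cox_pvalues(am, cohort.survival)
    return pd.DataFrame(cols)


def run_discovery(
    training: list[Cohort],
    test: list[Cohort],
    feature_sets: list[FeatureSet],
    sizes=discovery.COMBINATION_SIZES,
    top_k: int = discovery.TOP_K,
    cutoff: int = discovery.FREQ_CUTOFF,
    sign: int = +1,
    gene_level: bool = False,
    n_gene_features: int | None = None,
    assess_serial: bool = False,
) -> DiscoveryResult:
    """The integrated discovery procedure over training-cohort combinations.

    Features are screened per level (subpathway / pathway, optionally gene);
    each level gets its own top-``top_k`` lists and frequency report, and
    candidates are features appearing in >= ``cutoff`` of the combinations'
    lists.  With ``assess_serial=True`` the leading combination's serial
    cumulative sets are assessed on each test cohort by K=2 log-rank.
    """
    if not training:
        raise DataError("run_discovery needs at least one training cohort")
    combos = discovery.enumerate_combinations([c.name for c in training], sizes)

    by_level: dict[str, list[FeatureSet]] = {}
    for f in feature_sets:
        by_level.setdefault(f.level, []).append(f)
    if gene_level:
        universe = list(training[0].expression.index)
        by_level[GENE] = gene_level_features(universe, n_gene_features)

    activities: dict[str, ActivityMatrix] = {}
    pvalues, ipscores, top_lists, frequency, selected = {}, {}, {}, {}, {}
    for level, feats in sorted(by_level.items()):
        pmat = _screen_level(training, feats, sign, activities, level)
        ipmat = discovery.ip_score_table(pmat, combos)
        lists = {col: discovery.rank_and_topk(ipmat[col], k=top_k) for col in ipmat.columns}
        freq = discovery.frequency_select(lists, cutoff=cutoff)
        pvalues[level] = pmat
        ipscores[level] = ipmat
        top_lists[level] = lists
        frequency[level] = freq
        selected[level] = list(freq.index[freq["selected"]])

    result = DiscoveryResult(
        pvalues=pvalues,
        ipscores=ipscores,
        top_lists=top_lists,
        frequency=frequency,
        selected=selected,
        activities=activities,
    )

    if assess_serial and test:
        level = "subpathway" if "subpathway" in top_lists else sorted(top_lists)[0]
        full_combo = "+".join(c.name for c in training)
        ranked = top_lists[level].get(full_combo) or next(iter(top_lists[level].values()))
        rows = []
        feats = by_level[level]
        for cohort in test:
            am = score_matrix(cohort.expression, feats, sign=sign)
            for sset in discovery.serial_sets(ranked):
                chi2, p = discovery.assess_set_on_cohort(sset, am, cohort.survival)
                rows.append(
                    {"cohort": cohort.name, "set_size": len(sset), "chi2": chi2, "p": p}
                )
        result.serial_assessment = pd.DataFrame(rows)
    return result


@dataclass
class ValidationResult:
    estimates: list[StudyEstimate]
    pooled: MetaResult
    subgroups: dict[str, MetaResult]
    sensitivity: pd.DataFrame
    funnel: dict[str, pd.DataFrame]
    drug_correlations: pd.DataFrame | None = None
    response_test: tuple[float, float] | None = None


def per_cohort_estimates(
    cohorts: list[Cohort], signature: FeatureSet, sign: int = +1
) -> list[StudyEstimate]:
    """Univariate Cox log-HR of the signature's normalised activity, per cohort."""
    out = []
    for cohort in cohorts:
        am = score_matrix(cohort.expression, [signature], sign=sign)
        fit = cox_univariate_table(am.normalized.iloc[0], cohort.survival)
        if fit.flag:
            raise DataError(f"cohort {cohort.name}: Cox fit flagged ({fit.flag})")
        out.append(
            StudyEstimate(study=cohort.name, loghr=fit.coef, se=fit.se, subgroup=cohort.platform)
        )
    return out


def run_validation(
    cohorts: list[Cohort],
    signature: FeatureSet,
    drug_table: pd.DataFrame | None = None,
    response_table: pd.DataFrame | None = None,
    response_activity: pd.Series | None = None,
    b_permutations: int = drugs.DEFAULT_B,
    seed: int = 0,
    sign: int = +1,
) -> ValidationResult:
    """Meta-analytic and pharmacological validation of one signature.

    Per-cohort continuous-activity Cox estimates are pooled with fixed/random
    auto-selection, split into platform subgroups, stress-tested by
    leave-one-out, and exported as funnel data.  If a drug table is supplied
    (columns: subtype, activity, one IC50 column per drug), each drug's
    activity-IC50 Spearman correlation within the classical subtype is tested
    by the subset-permutation procedure; if response labels plus per-sample
    activity are supplied, response groups are compared by rank-sum.
    """
    estimates = per_cohort_estimates(cohorts, signature, sign=sign)
    pooled = meta.pool_auto(estimates)
    subgroups = meta.subgroup_pool(estimates)
    sensitivity = (
        meta.sensitivity_leave_one_out(estimates) if len(estimates) >= 3 else pd.DataFrame()
    )
    funnel = meta.funnel_data(estimates, pooled)

    drug_corr = None
    if drug_table is not None:
        mask = (drug_table["subtype"] == "classical").to_numpy()
        act = drug_table["activity"].to_numpy(float)
        rows = []
        drug_cols = [c for c in drug_table.columns if c not in ("subtype", "activity")]
        for i, drug in enumerate(drug_cols):
            ic50 = np.log10(drug_table[drug].to_numpy(float))
            res = drugs.subtype_permutation_test(
                act, ic50, mask, b=b_permutations, seed=seed + i
            )
            rows.append(
                {
                    "drug": drug,
                    "rho": res.observed_rho,
                    "p_permutation": res.p,
                    "n_below": res.n_below,
                    "b": res.b,
                    "two_sided_p": res.two_sided_p,
                }
            )
        drug_corr = pd.DataFrame(rows).set_index("drug")

    response = None
    if response_table is not None and response_activity is not None:
        common = response_table.index.intersection(response_activity.index)
        response = drugs.response_group_test(
            response_activity.loc[common], response_table.loc[common, "response"]
        )
    return ValidationResult(
        estimates=estimates,
        pooled=pooled,
        subgroups=subgroups,
        sensitivity=sensitivity,
        funnel=funnel,
        drug_correlations=drug_corr,
        response_test=response,
    )
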