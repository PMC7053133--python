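"""Core containers shared across the pipeline.

Expression and activity matrices are plain :class:`pandas.DataFrame` objects
(rows = genes or features, columns = samples); survival tables are DataFrames
indexed by sample id with ``time`` and ``event`` columns.  The thin dataclasses
here carry the metadata those frames cannot: feature-set membership, platform
tags, and fit/meta-analysis summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE = "gene"
SUBPATHWAY = "subpathway"
PATHWAY = "pathway"
LEVELS = (GENE, SUBPATHWAY, PATHWAY)

MICROARRAY = "microarray"
RNASEQ = "rnaseq"


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


class DataError(ValueError):
    """Malformed or degenerate input data."""


@dataclass(frozen=True)
class FeatureSet:
    """A named gene set at gene, subpathway, or pathway level.

    ``id`` follows KEGG-style conventions: ``path:XXXXX`` for pathways,
    ``path:XXXXX_j`` for subpathways (1-based ``j``), and the gene symbol
    itself for singleton gene-level features.  ``parent`` is the owning
    pathway id, or ``""`` for top-level features.
    """

    id: str
    level: str
    genes: frozenset[str]
    parent: str = ""

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown feature level {self.level!r}")
        if not self.genes:
            raise ValueError(f"feature set {self.id!r} has no genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class Cohort:
    """One study: an expression matrix plus its survival table.

    ``expression`` is genes x samples; ``survival`` is indexed by sample id
    with columns ``time`` (positive), ``event`` (0/1), optional covariates and
    a ``subtype`` label.  ``platform`` is ``microarray`` or ``rnaseq``.
    """

    name: str
    expression: pd.DataFrame
    survival: pd.DataFrame
    platform: str = MICROARRAY

    def __post_init__(self) -> None:
        if self.platform not in (MICROARRAY, RNASEQ):
            raise DataError(f"cohort {self.name}: unknown platform {self.platform!r}")
        if list(self.expression.columns) != list(self.survival.index):
            raise DataError(f"cohort {self.name}: expression samples != survival samples")
        t = self.survival["time"].to_numpy(float)
        e = self.survival["event"].to_numpy()
        if not np.all(t > 0):
            raise DataError(f"cohort {self.name}: survival times must be strictly positive")
        if not np.isin(e, (0, 1)).all():
            raise DataError(f"cohort {self.name}: event indicator must be 0/1")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]


@dataclass
class CoxFitResult:
    """Wald summary of a (partial-likelihood) proportional-hazards fit.

    ``flag`` is empty for a clean fit; otherwise it names the degeneracy
    (``no_events``, ``constant``, ``no_convergence``) and ``p`` is 1 so that
    large screening loops never crash on a single bad feature.
    """

    coef: float
    se: float
    p: float
    n: int
    n_events: int
    flag: str = ""

    @property
    def hr(self) -> float:
        return float(np.exp(self.coef))

    @property
    def ci(self) -> tuple[float, float]:
        lo = np.exp(self.coef - 1.96 * self.se)
        hi = np.exp(self.coef + 1.96 * self.se)
        return float(lo), float(hi)


@dataclass
class MetaResult:
    """Pooled log hazard ratio with heterogeneity diagnostics.

    ``model`` records whether fixed-effect or DerSimonian-Laird random-effects
    pooling produced the estimate; ``weights`` (summing to 1) are the
    per-study relative weights actually used.
    """

    pooled_loghr: float
    se: float
    q: float
    df: int
    i2: float
    tau2: float
    model: str
    weights: pd.Series
    flag: str = ""

    @property
    def pooled_hr(self) -> float:
        return float(np.exp(self.pooled_loghr))

    @property
    def ci_hr(self) -> tuple[float, float]:
        return (
            float(np.exp(self.pooled_loghr - 1.96 * self.se)),
            float(np.exp(self.pooled_loghr + 1.96 * self.se)),
        )

    @property
    def p(self) -> float:
        from scipy import stats

        z = self.pooled_loghr / self.se
        return float(2.0 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class StudyEstimate:
    """One study's log hazard ratio and its standard error."""

    study: str
    loghr: float
    se: float
    subgroup: str = ""

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise DataError(f"study {self.study}: SE must be positive")


@dataclass
class PermutationResult:
    """Outcome of the subtype-permutation correlation test.

    ``p = n_below / b`` counts null correlations strictly below the observed
    one (a left tail: only sensible when the observed correlation is
    negative, i.e. higher activity, lower IC50).
    """

    observed_rho: float
    b: int
    n_below: int
    p: float
    seed: int
    two_sided_p: float = float("nan")
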