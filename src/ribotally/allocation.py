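"""tRNA gene allocation among amino acids: M_tRNA = b0 + b1*N_AA + b2*CFS.

Within a genome, the number of tRNA genes serving an amino acid (M_tRNA)
rises with how often that amino acid is used in proteins (N_AA, total codon
count across all CDSs) and with its synonymous codon family size (CFS).
The model is fitted by ordinary least squares over the 19 standard amino
acids excluding methionine, whose initiator function inflates its tRNA
count independently of usage.  The fit report carries the full ANOVA
partition (model/residual/total sums of squares, F) and per-coefficient
standard errors, t statistics and two-sided p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .codons import STANDARD_AMINO_ACIDS, GeneticCode, UsageTable, codon_family_sizes
from .inventory import TranslationInventory

__all__ = [
    "AllocationRow",
    "AllocationFit",
    "AllocationWarning",
    "build_allocation_table",
    "fit_allocation_model",
    "read_allocation_tsv",
    "write_allocation_tsv",
]

_PREDICTORS = ("intercept", "n_aa", "cfs")


class AllocationWarning(UserWarning):
    pass


@dataclass(frozen=True)
class AllocationRow:
    """One amino acid's usage, codon family size and tRNA gene count."""

    amino_acid: str
    n_aa: int
    cfs: int
    m_trna: int

    def __post_init__(self) -> None:
        if self.amino_acid == "M":
            raise ValueError(
                "methionine is excluded from the allocation model "
                "(initiator function)"
            )
        if not 1 <= self.cfs <= 6:
            raise ValueError("codon family size must be in [1, 6]")


@dataclass
class AllocationFit:
    """OLS fit of the allocation model with ANOVA and t-tests."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    t_stats: dict[str, float]
    p_values: dict[str, float]
    ss_model: float
    ss_residual: float
    ss_total: float
    df_model: int
    df_residual: int
    df_total: int
    ms_model: float
    ms_residual: float
    f_stat: float
    f_p_value: float
    r_squared: float
    n_obs: int
    rows: list[AllocationRow] = field(default_factory=list, repr=False)

    @property
    def beta0(self) -> float:
        return self.coefficients["intercept"]

    @property
    def beta1(self) -> float:
        return self.coefficients["n_aa"]

    @property
    def beta2(self) -> float:
        return self.coefficients["cfs"]

    def predict(self, n_aa, cfs):
        return self.beta0 + self.beta1 * np.asarray(n_aa) + self.beta2 * np.asarray(cfs)


def build_allocation_table(
    inventory: TranslationInventory,
    usage: UsageTable,
    code: GeneticCode,
) -> list[AllocationRow]:
    """Join tRNA counts, amino-acid usage and CFS into model rows.

    Produces one row per standard amino acid except Met (19 under a
    complete annotation), alphabetically ordered.  Selenocysteine and
    unclassified tRNAs never enter.  Amino acids with tRNA genes but zero
    recorded usage are kept (with a warning) — dropping them would bias
    the usage effect.
    """
    cfs = codon_family_sizes(code)
    rows = []
    for aa in STANDARD_AMINO_ACIDS:
        if aa == "M":
            continue
        m = inventory.m_trna.get(aa, 0)
        n = usage.n_aa.get(aa, 0)
        if m > 0 and n == 0:
            warnings.warn(
                f"{inventory.species_label}: {m} tRNA gene(s) for {aa} but "
                "no codon usage recorded",
                AllocationWarning,
                stacklevel=2,
            )
        if m == 0 and n == 0:
            continue
        rows.append(AllocationRow(amino_acid=aa, n_aa=n, cfs=cfs[aa], m_trna=m))
    if not rows:
        warnings.warn(
            f"{inventory.species_label}: no amino acids left after "
            "exclusions; allocation table is empty",
            AllocationWarning,
            stacklevel=2,
        )
    return rows


def fit_allocation_model(rows: list[AllocationRow]) -> AllocationFit:
    """Ordinary least squares via the normal equations, with full ANOVA.

    The overall F tests the two-predictor model against the intercept-only
    model on (2, n-3) degrees of freedom; coefficient standard errors come
    from sigma2_hat * (X'X)^-1 with sigma2_hat = SS_residual / (n-3), and
    coefficient p-values are two-sided under t(n-3).
    """
    n = len(rows)
    if n < 4:
        raise ValueError(f"need at least 4 rows to fit the model, got {n}")
    y = np.array([r.m_trna for r in rows], dtype=float)
    x = np.column_stack(
        [
            np.ones(n),
            np.array([r.n_aa for r in rows], dtype=float),
            np.array([r.cfs for r in rows], dtype=float),
        ]
    )
    if np.linalg.matrix_rank(x) < 3:
        # name the offending pair for the caller
        corr = np.corrcoef(x[:, 1], x[:, 2])[0, 1]
        raise ValueError(
            "design matrix is rank deficient: n_aa and cfs are collinear "
            f"(r = {corr:.3f}) or constant"
        )
    xtx = x.T @ x
    beta = np.linalg.solve(xtx, x.T @ y)

    fitted = x @ beta
    resid = y - fitted
    ss_residual = float(resid @ resid)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_model = float(np.sum((fitted - y.mean()) ** 2))
    df_model, df_residual, df_total = 2, n - 3, n - 1
    ms_model = ss_model / df_model
    ms_residual = ss_residual / df_residual
    if ms_residual > 0:
        f_stat = ms_model / ms_residual
        f_p = float(stats.f.sf(f_stat, df_model, df_residual))
    else:
        f_stat, f_p = float("inf"), 0.0

    cov = ms_residual * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore"):
        t_vals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p_vals = 2.0 * stats.t.sf(np.abs(t_vals), df_residual)

    return AllocationFit(
        coefficients=dict(zip(_PREDICTORS, map(float, beta))),
        standard_errors=dict(zip(_PREDICTORS, map(float, se))),
        t_stats=dict(zip(_PREDICTORS, map(float, t_vals))),
        p_values=dict(zip(_PREDICTORS, map(float, p_vals))),
        ss_model=ss_model,
        ss_residual=ss_residual,
        ss_total=ss_total,
        df_model=df_model,
        df_residual=df_residual,
        df_total=df_total,
        ms_model=ms_model,
        ms_residual=ms_residual,
        f_stat=f_stat,
        f_p_value=f_p,
        r_squared=ss_model / ss_total if ss_total > 0 else 0.0,
        n_obs=n,
        rows=list(rows),
    )


def read_allocation_tsv(path) -> list[AllocationRow]:
    """Read an allocation table (columns amino_acid, n_aa, cfs, m_trna)."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t")
    required = {"amino_acid", "n_aa", "cfs", "m_trna"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"allocation table missing columns: {sorted(missing)}")
    return [
        AllocationRow(
            amino_acid=str(r.amino_acid),
            n_aa=int(r.n_aa),
            cfs=int(r.cfs),
            m_trna=int(r.m_trna),
        )
        for r in frame.itertuples()
    ]


def write_allocation_tsv(rows: list[AllocationRow], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {"amino_acid": r.amino_acid, "n_aa": r.n_aa, "cfs": r.cfs,
             "m_trna": r.m_trna}
            for r in rows
        ]
    ).to_csv(path, sep="\t", index=False)
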