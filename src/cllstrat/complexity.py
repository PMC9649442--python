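"""Genomic-complexity grouping by multiple correspondence analysis.

Seventeen genome-wide binary measures (mutation and indel counts, telomere
metrics binned at the cohort median; presence/absence of SV breakpoints,
CNAs, gains, losses, cnLOH, trisomy, aneuploidy and derived exclusions,
inversions, translocations, chromothripsis) enter an MCA: correspondence
analysis of the complete disjunctive (indicator) table, two categories per
variable. The variables contributing most to the retained dimensions are
selected, and patients are assigned to one of the eight complexity groups
(GC1–GC8) by the presence/absence pattern of the three selected variables
(canonically CN loss, CN gain, trisomy).

For Q binary variables the indicator table has J = 2Q categories and total
inertia (J - Q)/Q = 1; dimensions with eigenvalue above the mean (1/Q) are
retained for contribution ranking. No Benzécri correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The 17 genome-wide binary measures of the complexity analysis.
MCA_MEASURES = (
    "snv_count_bin",
    "indel_count_bin",
    "telomere_length_bin",
    "telomere_content_bin",
    "sv_breakpoint",
    "cna",
    "cn_gain",
    "cn_loss",
    "cnloh",
    "trisomy",
    "aneuploidy",
    "cn_gain_excl_trisomy",
    "cn_loss_excl_aneuploidy",
    "cnloh_excl_whole_chromosome",
    "inversion",
    "translocation",
    "chromothripsis",
)

#: The three measures that define the complexity groups.
GC_DEFINING_VARIABLES = ("cn_loss", "cn_gain", "trisomy")


@dataclass
class MCAResult:
    eigenvalues: np.ndarray                 # per-dimension inertia, non-increasing
    category_coordinates: pd.DataFrame      # categories x dims (principal)
    variable_contributions: pd.DataFrame    # variables x dims, columns sum to 1
    retained_dims: list[int]
    total_inertia: float
    dropped_constant: list[str]


def run_mca(matrix: pd.DataFrame) -> MCAResult:
    """Correspondence analysis of the complete disjunctive table.

    ``matrix`` is patients x binary variables. Constant columns are dropped
    with a warning entry in the result. The standardized residual matrix of
    the indicator table is decomposed by SVD; eigenvalues are squared
    singular values, category principal coordinates are scaled right
    singular vectors, and a variable's contribution to a dimension is the
    summed category contribution of its two categories.
    """
    if len(matrix) < 2:
        raise ValueError("MCA requires at least two patients")
    values = matrix.to_numpy(dtype=float)
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValueError("MCA input must be binary")
    keep = [c for c in matrix.columns if matrix[c].nunique() > 1]
    dropped = [c for c in matrix.columns if c not in keep]
    matrix = matrix[keep]
    n, q = matrix.shape
    if q == 0:
        raise ValueError("all variables constant; MCA undefined")

    # complete disjunctive coding: [absent, present] per variable
    cats: list[str] = []
    blocks = []
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        blocks.extend([1.0 - x, x])
        cats.extend([f"{col}=0", f"{col}=1"])
    Z = np.column_stack(blocks)

    P = Z / Z.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    _, sv, Vt = np.linalg.svd(S, full_matrices=False)
    # the number of non-trivial dimensions is at most J - Q
    n_dims = len(cats) - q
    sv = sv[:n_dims]
    Vt = Vt[:n_dims]
    eig = sv**2

    col_coords = (Vt.T / np.sqrt(c)[:, None]) * sv[None, :]
    # category contribution to a dimension: c_j * coord^2 / eigenvalue
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib_cat = (c[:, None] * col_coords**2) / np.where(eig > 0, eig, np.nan)[None, :]
    dims = [f"dim{i + 1}" for i in range(n_dims)]
    cat_df = pd.DataFrame(col_coords, index=cats, columns=dims)
    contrib_cat_df = pd.DataFrame(contrib_cat, index=cats, columns=dims)
    var_contrib = pd.DataFrame(
        {
            d: [
                contrib_cat_df.loc[f"{v}=0", d] + contrib_cat_df.loc[f"{v}=1", d]
                for v in matrix.columns
            ]
            for d in dims
        },
        index=list(matrix.columns),
    )
    total_inertia = float(eig.sum())
    mean_eig = total_inertia / n_dims if n_dims else 0.0
    retained = [i for i, e in enumerate(eig) if e > mean_eig] or ([0] if n_dims else [])
    return MCAResult(
        eigenvalues=eig,
        category_coordinates=cat_df,
        variable_contributions=var_contrib,
        retained_dims=retained,
        total_inertia=total_inertia,
        dropped_constant=dropped,
    )


def select_top_variables(result: MCAResult, k: int = 3) -> list[str]:
    """Top-k variables by eigenvalue-weighted contribution over the retained
    dimensions (i.e. share of the retained explained inertia); ties broken by
    input column order."""
    if k > len(result.variable_contributions):
        raise ValueError("k exceeds the number of variables")
    dims = [f"dim{i + 1}" for i in result.retained_dims]
    weights = {d: result.eigenvalues[i] for d, i in zip(dims, result.retained_dims)}
    totals = sum(
        result.variable_contributions[d] * w for d, w in weights.items()
    )
    order = {v: i for i, v in enumerate(result.variable_contributions.index)}
    ranked = sorted(totals.index, key=lambda v: (-totals[v], order[v]))
    return ranked[:k]


@dataclass
class GCAssignment:
    groups: pd.Series                     # patient -> GC1..GC8
    group_definition: dict[str, tuple[int, int, int]]
    variables: tuple[str, str, str]


def assign_gc_groups(
    matrix: pd.DataFrame, variables: tuple[str, str, str] = GC_DEFINING_VARIABLES
) -> GCAssignment:
    """Map each patient to one of 8 groups by its 3-bit pattern.

    Bit order (loss, gain, trisomy) read as a binary number:
    (0,0,0) -> GC1 ... (1,1,1) -> GC8.
    """
    missing = [v for v in variables if v not in matrix.columns]
    if missing:
        raise ValueError(f"variables not in matrix: {missing}")
    bits = matrix[list(variables)].to_numpy(dtype=int)
    codes = bits[:, 0] * 4 + bits[:, 1] * 2 + bits[:, 2]
    groups = pd.Series([f"GC{c + 1}" for c in codes], index=matrix.index, name="gc_group")
    definition = {
        f"GC{c + 1}": ((c >> 2) & 1, (c >> 1) & 1, c & 1) for c in range(8)
    }
    return GCAssignment(groups=groups, group_definition=definition, variables=tuple(variables))


def conventional_complexity(cna_counts: pd.Series | np.ndarray, threshold: int = 4) -> np.ndarray:
    """Conventional genomic complexity: at least ``threshold`` CNAs."""
    counts = np.asarray(cna_counts)
    if (counts < 0).any():
        raise ValueError("CNA counts must be nonnegative")
    return (counts >= threshold).astype(int)
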