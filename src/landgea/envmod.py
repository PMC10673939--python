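"""Environment tables: standardization, climate PCA, and forward selection
of non-collinear climate variables against the genotype matrix (an
ordiR2step-style stepwise RDA)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix
from .structure import PCAResult, _pca_core

GEO_COLUMNS = ("lat", "lon", "alt")
META_COLUMNS = ("sample", "site", "group")


@dataclass
class EnvTable:
    """Per-sample geography plus climate variables.

    ``table`` holds one row per genotyped sample; ``variables`` names the
    climate columns; geography (lat/lon/alt) stays on its raw scale even
    after standardization of the climate block.
    """

    table: pd.DataFrame
    variables: list[str]
    standardized: bool = False

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EnvTable":
        known = set(GEO_COLUMNS) | set(META_COLUMNS)
        variables = [c for c in frame.columns if c not in known]
        return cls(table=frame.copy(), variables=variables)

    @classmethod
    def read_tsv(cls, path: str) -> "EnvTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].tolist()

    def climate_matrix(self) -> np.ndarray:
        return self.table[self.variables].to_numpy(dtype=float)

    def geography_matrix(self) -> np.ndarray:
        return self.table[["lat", "lon"]].to_numpy(dtype=float)


def standardize_env(env: EnvTable) -> EnvTable:
    """Z-score every climate variable; constant variables are dropped with a
    warning naming them. Geography is left unscaled."""
    frame = env.table.copy()
    kept = []
    dropped = []
    for name in env.variables:
        col = frame[name].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        if sd == 0:
            dropped.append(name)
            frame = frame.drop(columns=[name])
            continue
        frame[name] = (col - col.mean()) / sd
        kept.append(name)
    if dropped:
        warnings.warn(f"dropped constant variables: {', '.join(dropped)}", stacklevel=2)
    return EnvTable(table=frame, variables=kept, standardized=True)


def env_pca(env: EnvTable) -> PCAResult:
    """Unit-scaled PCA of the (standardized) climate block."""
    if not env.standardized:
        env = standardize_env(env)
    X = env.climate_matrix()
    X = X - X.mean(axis=0)
    return _pca_core(X)


@dataclass
class SelectionTrace:
    """Forward-selection record: variables in order of entry, adjusted R2
    after each step, permutation p per step, and why selection stopped."""

    selected: list[str] = field(default_factory=list)
    adj_r2: list[float] = field(default_factory=list)
    p_values: list[float] = field(default_factory=list)
    stop_reason: str = ""
    global_adj_r2: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variable": self.selected, "adj_r2": self.adj_r2, "p_perm": self.p_values}
        )


def _adjusted_r2(r2: float, n: int, m: int) -> float:
    if n - m - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _explained_ss(Yc: np.ndarray, X: np.ndarray) -> float:
    """Squared Frobenius norm of the projection of Yc onto colspace(X)."""
    q, _ = np.linalg.qr(X - X.mean(axis=0))
    proj = q.T @ Yc
    return float(np.sum(proj**2))


def forward_select(
    g_imputed: GenotypeMatrix,
    env: EnvTable,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    max_steps: int | None = None,
) -> SelectionTrace:
    """Stepwise forward selection of climate variables for RDA of genotypes.

    At each step the unselected variable with the largest adjusted-R2 gain
    is tested by permutation (vegan-style marginal test: the candidate's
    contribution after the already-selected variables, with sample rows of
    the residualized candidate permuted). It enters only if the permutation
    p <= ``alpha`` and the running adjusted R2 stays at or below the
    full-model (all variables) adjusted R2; otherwise selection stops.
    Geography is not offered to the selection. ``max_steps`` caps the
    number of variables admitted (None = no cap).
    """
    if not env.standardized:
        env = standardize_env(env)
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives unstable permutation p-values", stacklevel=2)
    rng = np.random.default_rng(seed)
    Y = g_imputed.dosage
    Yc = Y - Y.mean(axis=0)
    total_ss = float(np.sum(Yc**2))
    n = Yc.shape[0]
    names = list(env.variables)
    E = env.climate_matrix()

    global_r2 = _explained_ss(Yc, E) / total_ss
    global_adj = _adjusted_r2(global_r2, n, len(names))

    trace = SelectionTrace(global_adj_r2=global_adj)
    remaining = list(range(len(names)))
    current_adj = 0.0

    while remaining:
        if max_steps is not None and len(trace.selected) >= max_steps:
            trace.stop_reason = "max_steps reached"
            break
        sel_idx = [names.index(v) for v in trace.selected]
        gains = []
        for j in remaining:
            cols = E[:, sel_idx + [j]]
            r2 = _explained_ss(Yc, cols) / total_ss
            gains.append(_adjusted_r2(r2, n, len(sel_idx) + 1))
        best_local = int(np.argmax(gains))
        best_j = remaining[best_local]
        best_adj = gains[best_local]
        if best_adj <= current_adj + 1e-12:
            trace.stop_reason = "no adjusted-R2 gain"
            break
        if best_adj > global_adj + 1e-12:
            trace.stop_reason = "global adjusted-R2 ceiling reached"
            break
        # marginal permutation test of the best candidate given the selected set
        if sel_idx:
            q, _ = np.linalg.qr(E[:, sel_idx] - E[:, sel_idx].mean(axis=0))
            resid_Y = Yc - q @ (q.T @ Yc)
            x = E[:, best_j] - E[:, best_j].mean()
            x = x - q @ (q.T @ x)
        else:
            resid_Y = Yc
            x = E[:, best_j] - E[:, best_j].mean()
        m_sel = len(sel_idx)
        norm2 = float(x @ x)
        if norm2 <= 0:
            trace.stop_reason = "candidate collinear with selected set"
            break
        resid_total = float(np.sum(resid_Y**2))

        def _pseudo_f(xv: np.ndarray) -> float:
            expl = float(np.sum((xv @ resid_Y) ** 2)) / float(xv @ xv)
            df_resid = n - m_sel - 2
            return (expl / 1.0) / ((resid_total - expl) / df_resid)

        f_obs = _pseudo_f(x)
        perms = np.stack([rng.permutation(x) for _ in range(n_perm)])
        expl = np.sum((perms @ resid_Y) ** 2, axis=1) / np.sum(perms * perms, axis=1)
        f_perm = expl / ((resid_total - expl) / (n - m_sel - 2))
        p = (1 + int(np.sum(f_perm >= f_obs))) / (n_perm + 1)
        if p > alpha:
            trace.stop_reason = f"candidate {names[best_j]} not significant (p={p:.4g})"
            break
        trace.selected.append(names[best_j])
        trace.adj_r2.append(best_adj)
        trace.p_values.append(p)
        current_adj = best_adj
        remaining.remove(best_j)
    else:
        trace.stop_reason = "all variables selected"
    return trace
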