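"""Hierarchical estimation of interval mean macular-thickness change.

The response is the change from the same participant/eye/sector non-pregnant
thickness, one row per (participant, eye, sector, pregnancy encounter).  The
model is a linear mixed-effects model with cell-mean fixed effects for the
three gestational intervals (optionally crossed with pregnancy group) and
random intercepts at three nested levels -- participant, eye within
participant, and sector within eye -- plus a residual whose correlation
decays continuously with the time separation of repeated measurements of the
same sector series (continuous-time AR(1): corr = rho ** |delta weeks|).

Estimation is residual (restricted) maximum likelihood.  The marginal
covariance is block diagonal by participant, so the REML deviance is
accumulated over participant blocks (vectorized over blocks of equal size)
and minimised with L-BFGS-B over log-variances and the logit of the weekly
correlation.  Confidence intervals on the fixed effects are Wald.

Variance components are reported but, being sensitive to the choice of
correlation family, carry less reliability than the fixed effects; the
correlation family itself (exponential decay in |delta weeks|) is a
configurable default, as the repeated-measures structure does not identify
the family from three encounters per series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trajectory import PREGNANCY_EPOCHS, Encounter

if TYPE_CHECKING:  # pragma: no cover
    from .io import ScanRecord

__all__ = [
    "GROUPS",
    "ConvergenceError",
    "IntervalEstimates",
    "build_long_table",
    "pool_hdp",
    "fit_interval_model",
]

logger = logging.getLogger(__name__)

#: Pregnancy groups in reporting order.
GROUPS: tuple[str, ...] = ("control", "denovo_hdp", "chtn_lot", "chtn_nolot")

#: Groups pooled as "hdp" by :func:`pool_hdp`.
HDP_GROUPS: frozenset[str] = frozenset({"denovo_hdp", "chtn_lot", "chtn_nolot"})

LONG_COLUMNS = ["participant_id", "eye", "sector", "epoch", "time_weeks", "change_um", "group"]


class ConvergenceError(RuntimeError):
    """REML optimisation failed; carries the iteration trace."""

    def __init__(self, message: str, trace: list[tuple[np.ndarray, float]]):
        super().__init__(message)
        self.trace = trace


def build_long_table(
    scans: Sequence["ScanRecord"],
    encounters: Iterable[Encounter],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """One row per (participant, eye, sector, pregnancy encounter).

    ``scans`` must already be the selected (better-of-two) records.  The
    non-pregnant baseline defines zero and contributes no rows; participants
    missing a baseline in either measured eye are dropped with a warning.
    """
    from .grid import SECTORS

    enc_by_id = {e.encounter_id: e for e in encounters}
    baselines: dict[tuple[str, str], "ScanRecord"] = {}
    pregnancy: list[tuple["ScanRecord", Encounter]] = []
    for scan in scans:
        enc = enc_by_id.get(scan.encounter_id)
        if enc is None:
            raise ValueError(f"scan references unknown encounter {scan.encounter_id!r}")
        if enc.epoch == "nonpregnant_baseline":
            baselines[(scan.participant_id, scan.eye)] = scan
        else:
            pregnancy.append((scan, enc))

    eyes_by_pid: dict[str, set[str]] = {}
    for scan, _ in pregnancy:
        eyes_by_pid.setdefault(scan.participant_id, set()).add(scan.eye)
    dropped = {
        pid for pid, eyes in eyes_by_pid.items()
        if any((pid, eye) not in baselines for eye in eyes)
    }
    if dropped:
        logger.warning("dropping %d participant(s) without a non-pregnant baseline: %s",
                       len(dropped), sorted(dropped))

    rows = []
    for scan, enc in pregnancy:
        pid = scan.participant_id
        if pid in dropped:
            continue
        if pid not in groups:
            raise ValueError(f"no group assignment for participant {pid!r}")
        base = baselines[(pid, scan.eye)]
        for s in SECTORS:
            rows.append((pid, scan.eye, s, enc.epoch, float(enc.gestational_age),
                         round(scan.sectors[s] - base.sectors[s], 2), groups[pid]))
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def pool_hdp(table: pd.DataFrame, label: str = "hdp") -> pd.DataFrame:
    """Relabel the three HDP groups as one pooled group."""
    out = table.copy()
    out["group"] = out["group"].map(lambda g: label if g in HDP_GROUPS else g)
    return out


@dataclass
class IntervalEstimates:
    """Fixed-effect estimates, epoch contrasts and variance components."""

    estimates: pd.DataFrame  # group, epoch, mean, se, ci_lo, ci_hi, p_vs_baseline
    contrasts: pd.DataFrame  # group, epoch_a, epoch_b, estimate, se, p
    variance_components: dict[str, float]  # participant, eye, sector, residual
    rho_week: float
    reml_deviance: float
    n_iter: int
    by_group: bool
    beta_cov: np.ndarray = field(repr=False)

    def estimate(self, group: str | None, epoch: str) -> pd.Series:
        df = self.estimates
        sel = df["epoch"] == epoch
        if group is not None:
            sel &= df["group"] == group
        hit = df[sel]
        if len(hit) != 1:
            raise KeyError(f"no unique estimate for group={group!r}, epoch={epoch!r}")
        return hit.iloc[0]

    def to_frame(self) -> pd.DataFrame:
        """Layout mirroring the interval table: one row per group x epoch with
        contrast p-values versus the earlier intervals."""
        pmap = {
            (r.group, r.epoch_a, r.epoch_b): r.p
            for r in self.contrasts.itertuples()
        }
        rows = []
        for r in self.estimates.itertuples():
            rows.append({
                "group": r.group,
                "epoch": r.epoch,
                "mean": r.mean,
                "ci_lo": r.ci_lo,
                "ci_hi": r.ci_hi,
                "p_vs_early": pmap.get((r.group, r.epoch, "early")),
                "p_vs_mid": pmap.get((r.group, r.epoch, "mid")),
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _prepare_blocks(table: pd.DataFrame, by_group: bool, require_all_epochs: bool = True):
    """Sort the table, build cell-mean design and per-participant block data."""
    df = table.sort_values(["participant_id", "eye", "sector", "time_weeks"], kind="mergesort")
    df = df.reset_index(drop=True)
    if df["epoch"].isin(("nonpregnant_baseline",)).any():
        raise ValueError("long table must not contain baseline rows")
    if not np.isfinite(df["change_um"]).all():
        raise ValueError("non-finite change values in long table")

    epochs = [e for e in PREGNANCY_EPOCHS if e in set(df["epoch"])]
    if require_all_epochs and len(epochs) < len(PREGNANCY_EPOCHS):
        missing = set(PREGNANCY_EPOCHS) - set(epochs)
        raise ValueError(f"all three gestational intervals must be represented; missing {sorted(missing)}")
    if by_group:
        group_order = [g for g in GROUPS if g in set(df["group"])]
        group_order += sorted(set(df["group"]) - set(group_order))
        cells = [(g, e) for g in group_order for e in epochs]
        cell_index = {c: i for i, c in enumerate(cells)}
        col = df.apply(lambda r: cell_index[(r["group"], r["epoch"])], axis=1).to_numpy()
    else:
        cells = [(None, e) for e in epochs]
        cell_index = {e: i for i, e in enumerate(epochs)}
        col = df["epoch"].map(cell_index).to_numpy()
    p = len(cells)
    X = np.zeros((len(df), p))
    X[np.arange(len(df)), col] = 1.0

    counts = df.groupby("group")["participant_id"].nunique() if by_group else None
    if by_group and (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"need >= 2 participants per estimated group; too few in {small}")

    blocks = []
    for _, idx in df.groupby("participant_id", sort=True).indices.items():
        idx = np.sort(idx)
        sub = df.iloc[idx]
        eye_codes = pd.factorize(sub["eye"])[0]
        series_codes = pd.factorize(sub["eye"].astype(str) + "|" + sub["sector"].astype(str))[0]
        t = sub["time_weeks"].to_numpy(float)
        same_eye = eye_codes[:, None] == eye_codes[None, :]
        same_series = series_codes[:, None] == series_codes[None, :]
        dt = np.abs(t[:, None] - t[None, :])
        blocks.append((idx, same_eye, same_series, dt))

    # Group blocks by size so the deviance can be evaluated batched.
    by_size: dict[int, list] = {}
    for blk in blocks:
        by_size.setdefault(len(blk[0]), []).append(blk)
    batches = []
    y = df["change_um"].to_numpy(float)
    for m, blks in sorted(by_size.items()):
        Me = np.stack([b[1] for b in blks])
        Ms = np.stack([b[2] for b in blks])
        Dt = np.stack([b[3] for b in blks])
        M = np.stack([np.column_stack([X[b[0]], y[b[0]]]) for b in blks])
        batches.append((Me, Ms, Dt, M))
    return df, cells, X, y, batches


def _reml_deviance(theta: np.ndarray, batches, p: int, fix_rho: float | None):
    sp2, se2, ss2, sr2 = np.exp(theta[:4])
    rho = fix_rho if fix_rho is not None else 1.0 / (1.0 + np.exp(-theta[4]))
    A = np.zeros((p + 1, p + 1))
    logdet = 0.0
    for Me, Ms, Dt, M in batches:
        corr = np.power(rho, Dt) if rho > 0 else (Dt == 0).astype(float)
        Sigma = sp2 + se2 * Me + ss2 * Ms + sr2 * (corr * Ms)
        sign, ld = np.linalg.slogdet(Sigma)
        if np.any(sign <= 0):
            return 1e12, None, None
        logdet += float(ld.sum())
        G = np.linalg.solve(Sigma, M)
        A += np.einsum("bij,bik->jk", M, G)
    Axx = A[:p, :p]
    bxy = A[:p, p]
    qyy = A[p, p]
    sign, ldA = np.linalg.slogdet(Axx)
    if sign <= 0:
        return 1e12, None, None
    try:
        beta = np.linalg.solve(Axx, bxy)
    except np.linalg.LinAlgError:
        return 1e12, None, None
    dev = logdet + ldA + (qyy - bxy @ beta)
    return float(dev), beta, Axx


def fit_interval_model(
    table: pd.DataFrame,
    by_group: bool = True,
    fix_rho: float | None = None,
    maxiter: int = 300,
    require_all_epochs: bool = True,
) -> IntervalEstimates:
    """REML fit of the three-level interval model; Wald 95% CIs.

    ``fix_rho`` pins the weekly residual correlation (e.g. 0.0 to switch the
    serial correlation off); otherwise it is profiled with the variance
    components.  Raises :class:`ConvergenceError` (with the iteration trace
    attached) if the optimiser does not report success.
    """
    df, cells, X, y, batches = _prepare_blocks(table, by_group, require_all_epochs)
    p = len(cells)

    v0 = max(float(np.var(y)), 1e-4)
    theta0 = np.log(np.full(4, v0 / 4.0))
    n_theta = 4 if fix_rho is not None else 5
    x0 = np.concatenate([theta0, [0.0]])[:n_theta]
    bounds = [(-12.0, 8.0)] * 4 + ([] if fix_rho is not None else [(-10.0, 8.0)])

    trace: list[tuple[np.ndarray, float]] = []

    def objective(th):
        full = th if fix_rho is not None else th
        dev, _, _ = _reml_deviance(np.asarray(full, float), batches, p, fix_rho)
        trace.append((np.array(th, float), dev))
        return dev

    res = optimize.minimize(
        objective, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-5},
    )
    if not res.success:
        # Finite-difference gradient noise can abort the line search near a
        # variance boundary; a simplex restart from the best point is robust.
        start = res.x if np.isfinite(res.fun) else x0
        res = optimize.minimize(
            objective, start, method="Nelder-Mead",
            options={"maxiter": 4000, "fatol": 1e-9, "xatol": 1e-7},
        )
        res.x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
    if not res.success:
        raise ConvergenceError(f"REML did not converge: {res.message}", trace)
    dev, beta, Axx = _reml_deviance(res.x, batches, p, fix_rho)
    if beta is None:
        raise ConvergenceError("REML deviance degenerate at optimum", trace)

    sp2, se2, ss2, sr2 = np.exp(res.x[:4])
    rho = fix_rho if fix_rho is not None else float(1.0 / (1.0 + np.exp(-res.x[4])))
    comps = {"participant": float(sp2), "eye": float(se2), "sector": float(ss2), "residual": float(sr2)}
    tiny = 1e-5 * sum(comps.values())
    for name, v in comps.items():
        if v < tiny:
            warnings.warn(f"variance component {name!r} estimated at the zero boundary", stacklevel=2)

    beta_cov = np.linalg.inv(Axx)
    se = np.sqrt(np.diag(beta_cov))
    z = beta / se
    # Wald intervals with a t reference on containment-type df (participants
    # minus group levels): the cell means are participant-level contrasts, and
    # the normal quantile undercovers at these cohort sizes.
    n_participants = df["participant_id"].nunique()
    n_groups = len({g for g, _ in cells})
    dof = max(n_participants - n_groups, 1)
    crit = float(stats.t.ppf(0.975, dof))
    est_rows = []
    for (g, e), b, s, zz in zip(cells, beta, se, z):
        est_rows.append({
            "group": g if by_group else "all",
            "epoch": e,
            "mean": float(b),
            "se": float(s),
            "ci_lo": float(b - crit * s),
            "ci_hi": float(b + crit * s),
            "p_vs_baseline": float(2 * stats.t.sf(abs(zz), dof)),
        })
    estimates = pd.DataFrame(est_rows)

    con_rows = []
    cell_pos = {c: i for i, c in enumerate(cells)}
    groups_here = sorted({g for g, _ in cells}, key=lambda g: [g2 for g2, _ in cells].index(g))
    epochs_here = [e for e in PREGNANCY_EPOCHS if (groups_here[0], e) in cell_pos]
    for g in groups_here:
        for i_b, eb in enumerate(epochs_here):
            for ea in epochs_here[i_b + 1:]:
                ia, ib = cell_pos[(g, ea)], cell_pos[(g, eb)]
                diff = beta[ia] - beta[ib]
                var = beta_cov[ia, ia] + beta_cov[ib, ib] - 2 * beta_cov[ia, ib]
                sd = float(np.sqrt(max(var, 0.0)))
                con_rows.append({
                    "group": g if by_group else "all",
                    "epoch_a": ea, "epoch_b": eb,
                    "estimate": float(diff), "se": sd,
                    "p": float(2 * stats.t.sf(abs(diff) / sd, dof)) if sd > 0 else float("nan"),
                })
    contrasts = pd.DataFrame(con_rows, columns=["group", "epoch_a", "epoch_b", "estimate", "se", "p"])

    return IntervalEstimates(
        estimates=estimates,
        contrasts=contrasts,
        variance_components=comps,
        rho_week=float(rho),
        reml_deviance=float(dev),
        n_iter=int(res.nit),
        by_group=by_group,
        beta_cov=beta_cov,
    )
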