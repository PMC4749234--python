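"""Two-state melting-curve analysis and incremental-parameter calibration.

The observable is the logarithm of the 530 nm fluorescence, modelled as a
two-baseline mixture weighted by the two-state bound fraction theta(T):

    logF(T) = theta * (a_b + b_b T) + (1 - theta) * (a_u + b_u T)

where the bound (duplex) baseline is the fluorescent one. theta follows the
van't Hoff equilibrium implied by (dH, dS):

* bimolecular, two complementary strands at total concentration C_T:
  K = theta / ((1 - theta)^2 * C_T / 2), giving K(Tm) = 4 / C_T at
  theta = 1/2 and the Tm formula dH / (dS + R ln(C_T/4)) - 273.15;
* unimolecular (self-fold): theta = K / (1 + K).

The calibration pipeline fits each replicate curve, averages the fitted
(dH, dS) per oligo pair, converts them into incremental observations
relative to the unlabelled-duplex prediction (with the d > 3 mean-offset
baseline adjustment), and solves the pooled nearest-neighbor decomposition
by SVD least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import lmfit
from scipy import stats

from .oligo import as_dna
from .params import NNParamTable, R_CAL, Z_MISMATCH_KEYS, write_param_files
from .thermo import duplex_thermo, gibbs_at, tm_bimolecular, tm_unimolecular, T0_K

R_KCAL = R_CAL / 1000.0


class MeltCurveError(ValueError):
    pass


class NoTransitionError(MeltCurveError):
    """The curve shows no melting transition in the scanned range."""


@dataclass
class MeltCurve:
    """One temperature-scanned log-fluorescence melting curve."""

    temps: np.ndarray  # degC, strictly increasing
    logF: np.ndarray
    ct: float = 2e-6
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        self.logF = np.asarray(self.logF, dtype=float)
        if self.temps.shape != self.logF.shape:
            raise MeltCurveError("temps and logF must have equal length")
        if self.temps.size < 10:
            raise MeltCurveError("melting curve needs >= 10 points")
        if not np.all(np.diff(self.temps) > 0):
            raise MeltCurveError("temperatures must be strictly increasing")


@dataclass(frozen=True)
class TwoStateFit:
    """Fitted two-state parameters of one melting curve."""

    dH: float               # kcal/mol
    dS: float               # cal/mol/K
    baseline_unbound: tuple[float, float]  # intercept, slope
    baseline_bound: tuple[float, float]
    rss: float
    molecularity: str
    ct: float

    @property
    def tm(self) -> float:
        if self.molecularity == "bimolecular":
            return tm_bimolecular(self.dH, self.dS, self.ct)
        return tm_unimolecular(self.dH, self.dS, self.ct, include_ct=False)

    def gibbs(self, T: float) -> float:
        return gibbs_at(self.dH, self.dS, T)


def bound_fraction(dH: float, dS: float, temps_c: np.ndarray, ct: float,
                   molecularity: str = "bimolecular") -> np.ndarray:
    """theta(T) for the two-state model (vectorised over temperature)."""
    tk = np.asarray(temps_c, dtype=float) + T0_K
    lnK = -(dH - tk * dS / 1000.0) / (R_KCAL * tk)
    lnK = np.clip(lnK, -500, 500)
    K = np.exp(lnK)
    if molecularity == "unimolecular":
        return K / (1.0 + K)
    a = K * ct / 2.0  # K * per-strand concentration
    # theta solves a*theta^2 - (2a+1)*theta + a = 0, bound branch in [0, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(a > 0, (2 * a + 1 - np.sqrt(4 * a + 1)) / (2 * np.maximum(a, 1e-300)), 0.0)
    return np.clip(theta, 0.0, 1.0)


def model_curve(temps_c: np.ndarray, dH: float, dS: float,
                baseline_unbound: tuple[float, float],
                baseline_bound: tuple[float, float],
                ct: float, molecularity: str = "bimolecular") -> np.ndarray:
    """Noise-free two-state log-fluorescence curve."""
    t = np.asarray(temps_c, dtype=float)
    theta = bound_fraction(dH, dS, t, ct, molecularity)
    au, bu = baseline_unbound
    ab, bb = baseline_bound
    return theta * (ab + bb * t) + (1.0 - theta) * (au + bu * t)


def neg_first_derivative(curve: MeltCurve) -> tuple[np.ndarray, np.ndarray]:
    """Five-point averaged negative slope of the melting curve.

    W(T_i) = -(1/5) * sum_{d=-2..2} (Y(T_{i-d}) - Y(T_{i-d-1})) /
    (T_{i-d} - T_{i-d-1}); the endpoints whose window is incomplete are
    omitted. Returns (temps, W).
    """
    t, y = curve.temps, curve.logF
    n = t.size
    if n < 6:
        raise MeltCurveError("need at least 6 points for the derivative")
    slopes = (y[1:] - y[:-1]) / (t[1:] - t[:-1])  # slope[k] over (k, k+1)
    idx = np.arange(3, n - 2)
    W = np.empty(idx.size)
    for out, i in enumerate(idx):
        # pairs (i-d-1, i-d) for d = -2..2 -> slope indices i-3 .. i+1
        W[out] = -np.mean(slopes[i - 3:i + 2])
    return t[idx], W


def _initial_guesses(curve: MeltCurve, molecularity: str, n_starts: int,
                     seed: int) -> list[dict]:
    t, y = curve.temps, curve.logF
    dt, W = neg_first_derivative(curve)
    peak = int(np.argmax(W))
    tm0 = float(dt[peak])
    lo = np.polyfit(t[-5:], y[-5:], 1)  # unbound (high-T) baseline
    hi = np.polyfit(t[:5], y[:5], 1)    # bound (low-T) baseline
    # transition width from the full-width-at-half-maximum of the derivative
    # peak (robust to noise); van't Hoff slope at Tm scales as dH / (R Tm^2)
    half = W[peak] / 2.0
    above = W >= half
    left = peak
    while left > 0 and above[left - 1]:
        left -= 1
    right = peak
    while right < W.size - 1 and above[right + 1]:
        right += 1
    width = max(float(dt[right] - dt[left]), 2.0)
    tm_k = tm0 + T0_K
    dh_width = -3.3 * R_KCAL * tm_k ** 2 / width
    # the first start uses the width heuristic; the rest spread over a fixed
    # enthalpy ladder (short to long duplexes) plus seeded jitter so the
    # best-RSS pick cannot be stranded in one basin
    ladder = [dh_width, -60.0, -100.0, -150.0, -220.0]
    rng = np.random.default_rng(seed)
    while len(ladder) < n_starts:
        ladder.append(dh_width * float(rng.uniform(0.5, 2.0)))
    guesses = []
    for dh in ladder[:max(n_starts, 1)]:
        if molecularity == "bimolecular":
            ds = 1000.0 * dh / tm_k - R_CAL * math.log(curve.ct / 4.0)
        else:
            ds = 1000.0 * dh / tm_k
        guesses.append({
            "dH": dh, "dS": ds,
            "au": float(lo[1]), "bu": float(lo[0]),
            "ab": float(hi[1]), "bb": float(hi[0]),
        })
    return guesses


def two_state_fit(curve: MeltCurve, molecularity: str = "bimolecular",
                  n_starts: int = 5, seed: int = 0) -> TwoStateFit:
    """Nonlinear least-squares fit of the two-state model to one curve.

    Multi-start: the first start is seeded from the derivative peak (Tm) and
    a transition-width heuristic (dH), the rest jitter dH by a seeded RNG;
    the best residual sum of squares wins.
    """
    t, y = curve.temps, curve.logF
    span = float(np.max(y) - np.min(y))
    theta_span = None
    best = None
    for guess in _initial_guesses(curve, molecularity, n_starts, seed):
        params = lmfit.Parameters()
        params.add("dH", value=guess["dH"], max=-1.0)
        params.add("dS", value=guess["dS"], max=0.0)
        for k in ("au", "bu", "ab", "bb"):
            params.add(k, value=guess[k])

        def resid(p):
            return model_curve(t, p["dH"].value, p["dS"].value,
                               (p["au"].value, p["bu"].value),
                               (p["ab"].value, p["bb"].value),
                               curve.ct, molecularity) - y

        try:
            res = lmfit.minimize(resid, params, method="leastsq")
        except Exception:
            continue
        rss = float(np.sum(res.residual ** 2))
        if best is None or rss < best[0]:
            best = (rss, res.params)
    if best is None:
        raise NoTransitionError("two-state fit failed on every start")
    rss, p = best
    fit = TwoStateFit(
        dH=float(p["dH"].value), dS=float(p["dS"].value),
        baseline_unbound=(float(p["au"].value), float(p["bu"].value)),
        baseline_bound=(float(p["ab"].value), float(p["bb"].value)),
        rss=rss, molecularity=molecularity, ct=curve.ct,
    )
    theta_span = bound_fraction(fit.dH, fit.dS, t, curve.ct, molecularity)
    if span < 1e-3 or float(theta_span.max() - theta_span.min()) < 0.2:
        raise NoTransitionError(
            "no transition: the curve is flat or the transition lies outside "
            f"the scanned range ({t[0]:.1f}-{t[-1]:.1f} degC)")
    return fit


class TwoStateModel:
    """Model object wrapping :func:`two_state_fit` for one melting curve."""

    def __init__(self, curve: MeltCurve, molecularity: str = "bimolecular"):
        self.curve = curve
        self.molecularity = molecularity

    def fit(self, n_starts: int = 5, seed: int = 0) -> TwoStateFit:
        return two_state_fit(self.curve, self.molecularity, n_starts, seed)


# ---------------------------------------------------------------------------
# incremental observations and regression


@dataclass(frozen=True)
class IncrementObservation:
    """One labelled-duplex increment relative to the unlabelled prediction.

    ``classes`` lists the parameter classes this observation is a sum of
    (e.g. ``("NZ/AN",)`` after the known match-side context has been
    subtracted); ``distance_label_mismatch`` is in nt (None = full match).
    """

    ddH: float
    ddS: float
    classes: tuple[str, ...]
    context: str = ""
    distance_label_mismatch: int | None = None

    @property
    def ddG37(self) -> float:
        return gibbs_at(self.ddH, self.ddS, 37.0)

    @property
    def ddG60(self) -> float:
        return gibbs_at(self.ddH, self.ddS, 60.0)


def baseline_adjust(predicted_dna: tuple[float, float],
                    predicted_echo_far: list[tuple[float, float]],
                    observed_echo_far: list[tuple[float, float]]
                    ) -> tuple[tuple[float, float], bool]:
    """Positionally adjust a predicted unlabelled-duplex (dH, dS).

    For one base composition, the adjusted prediction is the raw prediction
    plus the mean observed-minus-predicted offset over labelled duplexes of
    the same composition whose label sits more than 3 nt from the mismatch:

        adjusted = predicted + (1/N) * sum_{d>3} (observed - predicted).

    Returns ``(adjusted, True)``; with no qualifying pair the unadjusted
    prediction is returned flagged ``(predicted, False)``.
    """
    if len(predicted_echo_far) != len(observed_echo_far):
        raise MeltCurveError("predicted/observed far-label lists differ in length")
    if not observed_echo_far:
        return predicted_dna, False
    dh_off = float(np.mean([o[0] - p[0] for o, p in
                            zip(observed_echo_far, predicted_echo_far)]))
    ds_off = float(np.mean([o[1] - p[1] for o, p in
                            zip(observed_echo_far, predicted_echo_far)]))
    return (predicted_dna[0] + dh_off, predicted_dna[1] + ds_off), True


def nn_decomposition(observations: list[IncrementObservation],
                     classes: list[str] | None = None) -> pd.DataFrame:
    """SVD least-squares decomposition of increments into per-class terms.

    Each observation's increment is modelled as the sum of its listed
    classes; the regression is run separately on ddH, ddS, ddG37 and ddG60.
    Returns a DataFrame indexed by class with ``<qty>`` and ``<qty>_se``
    columns. A rank-deficient design raises ``MeltCurveError`` naming the
    unidentifiable classes.
    """
    if not observations:
        raise MeltCurveError("no observations")
    if classes is None:
        classes = sorted({c for o in observations for c in o.classes})
    X = np.zeros((len(observations), len(classes)))
    for i, o in enumerate(observations):
        for c in o.classes:
            X[i, classes.index(c)] += 1.0
    rank = np.linalg.matrix_rank(X)
    if rank < len(classes):
        # classes whose coefficient lies in the null space are unidentifiable
        _, s, vt = np.linalg.svd(X)
        null = vt[rank:]
        bad = [classes[j] for j in range(len(classes))
               if np.any(np.abs(null[:, j]) > 1e-8)]
        raise MeltCurveError(f"rank-deficient design; unidentifiable classes: {bad}")
    out = {}
    xtx_inv = np.linalg.pinv(X.T @ X)
    dof = len(observations) - len(classes)
    for qty in ("ddH", "ddS", "ddG37", "ddG60"):
        y = np.array([getattr(o, qty) for o in observations])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        if dof > 0:
            sigma2 = float(resid @ resid) / dof
            se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
        else:
            se = np.full(len(classes), np.nan)
        out[qty] = beta
        out[qty + "_se"] = se
    return pd.DataFrame(out, index=pd.Index(classes, name="class"))


def ttest_two_group(a, b) -> tuple[float, float]:
    """Classic unpaired two-tailed Student's t-test (equal variances)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise MeltCurveError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise MeltCurveError("degenerate (zero) pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# end-to-end calibration


def read_curve_file(path: str | Path) -> pd.DataFrame:
    """Tab-delimited curves: curve_id, replicate, temp_C, logF."""
    df = pd.read_csv(path, sep="\t")
    required = {"curve_id", "replicate", "temp_C", "logF"}
    if df.empty or not required <= set(df.columns):
        raise MeltCurveError(
            f"curve file {path} must be tab-delimited with columns {sorted(required)}")
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Tab-delimited manifest: curve_id, probe_seq, label_pos_from_3p,
    target_seq, ct_molar."""
    df = pd.read_csv(path, sep="\t")
    required = {"curve_id", "probe_seq", "label_pos_from_3p", "target_seq", "ct_molar"}
    if df.empty or not required <= set(df.columns):
        raise MeltCurveError(
            f"manifest {path} must be tab-delimited with columns {sorted(required)}")
    return df


def _mismatch_positions(probe_seq: str, target: str) -> list[int]:
    from .oligo import complement
    dna = as_dna(probe_seq)
    return [i for i in range(len(dna)) if complement(dna[i]) != target[i]]


def _observation_from_pair(probe_seq: str, target: str, obs: tuple[float, float],
                           table: NNParamTable, context: str = ""
                           ) -> IncrementObservation | None:
    """Build the pooled-class increment observation for one labelled duplex.

    Subtracts the adjusted unlabelled prediction and any *known* match-side
    label context, leaving the response attributed to the pooled
    mismatch-adjacent class. Returns None for pairs that carry no
    mismatch-adjacent label (they inform the baseline, not the regression).
    """
    zpos = probe_seq.index("Z")
    mms = _mismatch_positions(probe_seq, target)
    if not mms:
        return None
    d = min(abs(zpos - m) for m in mms)
    if d != 1:
        return None
    side_5p = (zpos - 1) in mms
    cls = "NZ/AN" if side_5p else "ZN/NA"
    # known match-side context on the other flank
    dh_known = ds_known = 0.0
    if side_5p and zpos < len(probe_seq) - 1:
        dh_known, ds_known = table.z_match_increments["Z" + probe_seq[zpos + 1]]
    elif not side_5p and zpos > 0:
        dh_known, ds_known = table.z_match_increments[probe_seq[zpos - 1] + "Z"]
    return IncrementObservation(
        ddH=obs[0] - dh_known, ddS=obs[1] - ds_known,
        classes=(cls,), context=context, distance_label_mismatch=d)


def calibrate(curve_path: str | Path, manifest_path: str | Path,
              table: NNParamTable, out_dir: str | Path | None = None,
              n_starts: int = 5, seed: int = 0) -> pd.DataFrame:
    """Full calibration pipeline: curves -> pooled label increments.

    1. fit every replicate curve with the two-state model and average the
       fitted (dH, dS) per oligo pair;
    2. per target (base composition), adjust the predicted unlabelled-duplex
       parameters by the mean observed-minus-predicted offset of far-label
       (d > 3) pairs;
    3. convert mismatch-adjacent (d = 1) pairs into pooled-class increment
       observations and solve the SVD regression;
    4. optionally write an updated parameter directory
       (z_mismatch provenance = ``calibrated``).

    Returns the regression table from :func:`nn_decomposition`.
    """
    curves = read_curve_file(curve_path)
    manifest = read_manifest(manifest_path).set_index("curve_id")

    fitted: dict[str, tuple[float, float]] = {}
    for curve_id, grp in curves.groupby("curve_id", sort=True):
        if curve_id not in manifest.index:
            raise MeltCurveError(f"curve {curve_id!r} missing from manifest")
        ct = float(manifest.loc[curve_id, "ct_molar"])
        fits = []
        for _, rep in grp.groupby("replicate", sort=True):
            rep = rep.sort_values("temp_C")
            mc = MeltCurve(rep["temp_C"].to_numpy(), rep["logF"].to_numpy(), ct=ct)
            try:
                fits.append(two_state_fit(mc, "bimolecular", n_starts, seed))
            except MeltCurveError as exc:
                raise MeltCurveError(f"curve {curve_id!r}: {exc}") from exc
        fitted[curve_id] = (float(np.mean([f.dH for f in fits])),
                            float(np.mean([f.dS for f in fits])))

    # group pairs by target sequence (base composition)
    by_target: dict[str, list[str]] = {}
    for curve_id in fitted:
        by_target.setdefault(str(manifest.loc[curve_id, "target_seq"]), []).append(curve_id)

    observations: list[IncrementObservation] = []
    for target, ids in sorted(by_target.items()):
        far_pred, far_obs = [], []
        for cid in ids:
            probe = str(manifest.loc[cid, "probe_seq"])
            zpos = probe.index("Z")
            mms = _mismatch_positions(probe, target)
            d = min((abs(zpos - m) for m in mms), default=None)
            if d is not None and d <= 3:
                continue
            pred = duplex_thermo(probe, target, table, ct=float(manifest.loc[cid, "ct_molar"]))
            far_pred.append((pred.dH, pred.dS))
            far_obs.append(fitted[cid])
        for cid in ids:
            probe = str(manifest.loc[cid, "probe_seq"])
            ct = float(manifest.loc[cid, "ct_molar"])
            pred_dna = duplex_thermo(as_dna(probe), target, table, ct=ct)
            adj, _flag = baseline_adjust((pred_dna.dH, pred_dna.dS), far_pred, far_obs)
            obs_inc = (fitted[cid][0] - adj[0], fitted[cid][1] - adj[1])
            o = _observation_from_pair(probe, target, obs_inc, table,
                                       context=f"{cid}:{probe}")
            if o is not None:
                observations.append(o)

    if not observations:
        raise MeltCurveError("no mismatch-adjacent labelled pairs in the input")
    result = nn_decomposition(observations, classes=list(Z_MISMATCH_KEYS))

    if out_dir is not None:
        new_table = NNParamTable(
            wc_stacks=dict(table.wc_stacks), mm_stacks=dict(table.mm_stacks),
            terminal_mm=dict(table.terminal_mm), initiation=dict(table.initiation),
            z_match_increments=dict(table.z_match_increments),
            z_mismatch_increments={
                k: (float(result.loc[k, "ddH"]), float(result.loc[k, "ddS"]))
                for k in Z_MISMATCH_KEYS},
            loop_ds=dict(table.loop_ds), salt=table.salt,
            provenance={**table.provenance,
                        **{k: "calibrated" for k in Z_MISMATCH_KEYS}},
        )
        new_table.validate()
        write_param_files(new_table, out_dir)
    return result
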