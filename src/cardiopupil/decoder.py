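"""Naive Bayesian decoding of respond/withhold from pre-stimulus baselines.

Baselines (pupil area PA, heart rate HR, heart-rate variability HRV) are
discretized into 15 equal-width bins per session. The decoder evaluates the
posterior over the binary behavioral outcome R (responded / withheld) via
chain-rule factorizations whose first listed predictor plays the target
role and the rest condition it:

    P(R | X)       ∝ P(X | R) · P(R)
    P(R | X, Y)    ∝ P(X | Y, R) · P(R | Y)
    P(R | X, Y, Z) ∝ P(X | Y, Z, R) · P(R | Y, Z)

Every conditional is estimated from smoothed counts with add-one (Laplace)
smoothing, P̂(A|B) = (D_{B,A} + 1)/(D_B + N_A), where N_A is the number of
possible values of the predicted variable A (2 for R, 15 per baseline bin
axis) so each conditional sums to one. Evaluation is leave-one-out
cross-validation with MAP prediction; chance is the LOOCV accuracy of the
prior-only decoder on the same trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DecoderModel",
    "DecodeResult",
    "OverlapMetrics",
    "discretize",
    "laplace_smooth",
    "fit_decoder",
    "posterior_response",
    "predict_map",
    "loocv_evaluate",
    "overlap_metrics",
    "decoder_vs_criterion",
]

N_BINS_DEFAULT = 15


def discretize(values, n_bins: int = N_BINS_DEFAULT, edges=None):
    """Equal-width binning over [min, max]; returns (0-based indices, edges).

    With supplied ``edges``, out-of-range values clamp to the extreme bins.
    """
    v = np.asarray(values, float)
    if edges is None:
        lo, hi = float(np.min(v)), float(np.max(v))
        if hi == lo:
            raise ValueError("constant values cannot be discretized without edges")
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        edges = np.asarray(edges, float)
        n_bins = len(edges) - 1
    idx = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, n_bins - 1)
    return idx.astype(int), edges


def laplace_smooth(count_ab, count_b, n_values):
    """Add-one smoothed conditional estimate (count_ab + 1)/(count_b + n_values)."""
    return (np.asarray(count_ab, float) + 1.0) / (np.asarray(count_b, float) + n_values)


@dataclass
class DecoderModel:
    """Count tables sufficient for the factorized posterior.

    ``counts`` has axes (response=2, target_bins, *conditioning_bins) in the
    order of ``predictors``; predictors[0] is the factorization's target.
    """

    predictors: tuple
    n_bins: int
    edges: dict
    counts: np.ndarray
    n_trials: int

    def smoothed_prior(self) -> float:
        n1 = self.counts[1].sum()
        return laplace_smooth(n1, self.n_trials, 2)

    def conditional_tables(self) -> dict:
        """Fully smoothed P(target|cond,R) and P(R|cond) tables (diagnostics).

        Each distribution sums to 1 over its predicted axis.
        """
        c = self.counts
        d_cond_r = c.sum(axis=1)                      # (2, *cond)
        like = (c + 1.0) / (d_cond_r[:, None, ...] + self.n_bins)
        p_r = (d_cond_r + 1.0) / (d_cond_r.sum(axis=0, keepdims=True) + 2.0)
        return {"p_target_given_cond_resp": like, "p_resp_given_cond": p_r}


@dataclass
class DecodeResult:
    posterior: np.ndarray
    predicted: np.ndarray
    true: np.ndarray
    accuracy: float
    chance: float
    above_chance: float
    correct_idx: np.ndarray = field(default=None)


@dataclass
class OverlapMetrics:
    pct_overlap: float
    normalized_overlap: float = None


def _as_bin_matrix(baselines, predictors, n_bins, edges=None):
    """Bin each predictor column; returns (n_trials × n_pred ints, edges dict)."""
    if isinstance(baselines, pd.DataFrame):
        data = {p: baselines[p].to_numpy(dtype=float) for p in predictors}
    else:
        data = {p: np.asarray(baselines[p], float) for p in predictors}
    edges = dict(edges) if edges else {}
    cols = []
    for p in predictors:
        idx, e = discretize(data[p], n_bins=n_bins, edges=edges.get(p))
        edges[p] = e
        cols.append(idx)
    return np.column_stack(cols), edges


def fit_decoder(baselines, responded, predictor_set, edges=None,
                n_bins: int = N_BINS_DEFAULT) -> DecoderModel:
    """Count-table fit over (response × predictor bins).

    ``baselines`` is a DataFrame (or mapping of arrays) holding the columns
    named in ``predictor_set``; ``responded`` is boolean per trial. Smoothing
    is applied at evaluation time, so absent classes are handled gracefully.
    """
    predictors = tuple(predictor_set)
    resp = np.asarray(responded, bool)
    if resp.size == 0:
        raise ValueError("empty training set")
    bins, edges = _as_bin_matrix(baselines, predictors, n_bins, edges)
    shape = (2,) + (n_bins,) * len(predictors)
    counts = np.zeros(shape)
    np.add.at(counts, (resp.astype(int), *bins.T), 1.0)
    return DecoderModel(predictors=predictors, n_bins=n_bins, edges=edges,
                        counts=counts, n_trials=int(resp.size))


def posterior_response(model: DecoderModel, trial_bins) -> float:
    """P(respond | predictors) for one trial's bin indices.

    Numerator per class r: P̂(target_bin | cond_bins, r) · P̂(r | cond_bins),
    each term Laplace-smoothed; the denominator normalizes over the two
    response classes.
    """
    tb = tuple(int(b) for b in np.atleast_1d(trial_bins))
    target, cond = tb[0], tb[1:]
    num = np.empty(2)
    for r in (0, 1):
        block = model.counts[(r, slice(None)) + cond]      # counts over target axis
        d_cond_r = block.sum()
        like = laplace_smooth(block[target], d_cond_r, model.n_bins)
        d_cond = model.counts[(slice(None), slice(None)) + cond].sum()
        p_r = laplace_smooth(d_cond_r, d_cond, 2)
        num[r] = like * p_r
    return float(num[1] / num.sum())


def predict_map(posterior: float, smoothed_prior: float = 0.5) -> bool:
    """MAP label: respond iff posterior > 0.5; an exact tie falls back to the
    class with the larger smoothed prior (respond when the prior also ties)."""
    if posterior > 0.5:
        return True
    if posterior < 0.5:
        return False
    return smoothed_prior >= 0.5


def _loocv_pass(bins, resp, n_bins, predictors):
    """One LOOCV sweep over pre-binned trials; returns (posterior, predicted)."""
    n = resp.size
    shape = (2,) + (n_bins,) * bins.shape[1]
    counts = np.zeros(shape)
    np.add.at(counts, (resp.astype(int), *bins.T), 1.0)
    model = DecoderModel(predictors=predictors, n_bins=n_bins, edges={},
                         counts=counts, n_trials=n)
    posterior = np.empty(n)
    predicted = np.empty(n, dtype=bool)
    for i in range(n):
        cell = (int(resp[i]), *bins[i])
        model.counts[cell] -= 1.0
        model.n_trials -= 1
        posterior[i] = posterior_response(model, bins[i])
        predicted[i] = predict_map(posterior[i], model.smoothed_prior())
        model.counts[cell] += 1.0
        model.n_trials += 1
    return posterior, predicted


def loocv_evaluate(baselines, responded, predictor_set,
                   n_bins: int = N_BINS_DEFAULT, edges_per_fold: bool = False,
                   chance_method: str = "prior", n_permutations: int = 3,
                   seed: int = 0) -> DecodeResult:
    """Leave-one-out evaluation of the factorized decoder.

    Bin edges are fixed from the whole session (the discretization is a
    per-session construct) unless ``edges_per_fold`` recomputes them from
    each training fold.

    ``chance_method`` controls the reference subtracted to form
    ``above_chance``:

    * ``"prior"`` — LOOCV accuracy of the prior-only (majority) decoder.
      Simple, but a binned decoder sits slightly *below* this reference when
      the predictors are pure noise, because deviating from the majority
      vote on noise has an expected cost the prior decoder never pays.
    * ``"permutation"`` — mean LOOCV accuracy of the same decoder over
      ``n_permutations`` label shuffles (seeded). Shares the decoder's
      overfitting behavior, so above-chance is centred on zero for
      uninformative predictors.
    """
    predictors = tuple(predictor_set)
    resp = np.asarray(responded, bool)
    n = resp.size
    if n < 3:
        raise ValueError("LOOCV needs at least 3 trials")
    if edges_per_fold:
        if isinstance(baselines, pd.DataFrame):
            frame = baselines
        else:
            frame = pd.DataFrame({p: np.asarray(baselines[p], float) for p in predictors})
        posterior = np.empty(n)
        predicted = np.empty(n, dtype=bool)
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            model = fit_decoder(frame[mask], resp[mask], predictors, n_bins=n_bins)
            tb, _ = _as_bin_matrix(frame.iloc[[i]], predictors, n_bins, model.edges)
            posterior[i] = posterior_response(model, tb[0])
            predicted[i] = predict_map(posterior[i], model.smoothed_prior())
        full = fit_decoder(baselines, resp, predictors, n_bins=n_bins)
        bins, _ = _as_bin_matrix(baselines, predictors, n_bins, full.edges)
    else:
        full = fit_decoder(baselines, resp, predictors, n_bins=n_bins)
        bins, _ = _as_bin_matrix(baselines, predictors, n_bins, full.edges)
        posterior, predicted = _loocv_pass(bins, resp, n_bins, predictors)
    correct = predicted == resp
    accuracy = float(correct.mean())

    if chance_method == "prior":
        # per fold, predict the smoothed-majority class of the training set
        n_resp = int(resp.sum())
        prior_pred = np.empty(n, dtype=bool)
        for i in range(n):
            p = (n_resp - int(resp[i]) + 1.0) / (n - 1 + 2.0)
            prior_pred[i] = predict_map(p, p)
        chance = float((prior_pred == resp).mean())
    elif chance_method == "permutation":
        rng = np.random.default_rng(seed)
        accs = []
        for _ in range(n_permutations):
            perm = rng.permutation(resp)
            _, pred_perm = _loocv_pass(bins, perm, n_bins, predictors)
            accs.append(np.mean(pred_perm == perm))
        chance = float(np.mean(accs))
    else:
        raise ValueError(f"unknown chance_method {chance_method!r}")
    return DecodeResult(posterior=posterior, predicted=predicted, true=resp,
                        accuracy=accuracy, chance=chance,
                        above_chance=accuracy - chance,
                        correct_idx=np.nonzero(correct)[0])


def overlap_metrics(correct_a, correct_b, accuracy_a: float = None,
                    accuracy_b: float = None) -> OverlapMetrics:
    """Shared correctly-predicted trials between two decoders.

    pct_overlap = |A∩B| / ((|A|+|B|)/2) × 100. With both accuracies given
    (fractions in (0, 1]), normalized_overlap = pct_overlap / (100 × mean
    accuracy), a dimensionless ratio that is 1 when the overlap is exactly
    what the accuracies alone would force.
    """
    a = set(np.asarray(correct_a).tolist())
    b = set(np.asarray(correct_b).tolist())
    if not a and not b:
        warnings.warn("both correct-trial sets empty; overlap defined as 0")
        return OverlapMetrics(pct_overlap=0.0)
    pct = len(a & b) / ((len(a) + len(b)) / 2.0) * 100.0
    norm = None
    if accuracy_a is not None and accuracy_b is not None:
        mean_acc = (accuracy_a + accuracy_b) / 2.0
        if mean_acc <= 0:
            raise ValueError("accuracies must be positive for normalization")
        norm = pct / (100.0 * mean_acc)
    return OverlapMetrics(pct_overlap=pct, normalized_overlap=norm)


def decoder_vs_criterion(sessions) -> pd.DataFrame:
    """Per-session decoder accuracies and PA/HR overlap, joined to criterion.

    ``sessions`` is an iterable of dicts with keys ``baselines`` (table with
    pa/hr columns), ``responded``, and ``criterion``. The output table feeds
    quadratic fits of accuracy and overlap against decision criterion.
    """
    rows = []
    for k, s in enumerate(sessions):
        res_pa = loocv_evaluate(s["baselines"], s["responded"], ("pa",))
        res_hr = loocv_evaluate(s["baselines"], s["responded"], ("hr",))
        ov = overlap_metrics(res_pa.correct_idx, res_hr.correct_idx,
                             res_pa.accuracy, res_hr.accuracy)
        rows.append({
            "session": s.get("session", k),
            "criterion": s["criterion"],
            "accuracy_pa": res_pa.accuracy,
            "accuracy_hr": res_hr.accuracy,
            "above_chance_pa": res_pa.above_chance,
            "above_chance_hr": res_hr.above_chance,
            "pct_overlap": ov.pct_overlap,
            "normalized_overlap": ov.normalized_overlap,
        })
    if len(rows) < 3:
        raise ValueError("decoder_vs_criterion needs at least 3 sessions")
    return pd.DataFrame(rows)
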