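"""Dose-matrix screen scoring: HSA excess, binarization, confusion metrics,
and the Monte-Carlo random prediction baseline.

The highest-single-agent (HSA) excess of a combination cell at doses
(a, b) is ``V_AB(a, b) - min(V_A(a), V_B(b))`` where viabilities are
fractions of the untreated control.  A pair is observed-synergistic when
its mean excess over all combination cells is <= the cutoff (default
-0.11, inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_CUTOFF = -0.11


class ScreenError(ValueError):
    pass


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))


@dataclass(frozen=True)
class ScreenRecord:
    """One drug pair's dose grid for one cell line.

    ``single_a``/``single_b`` map dose -> viability; ``combo`` maps
    (dose_a, dose_b) -> viability.
    """

    cell_line: str
    drug_a: str
    drug_b: str
    single_a: dict
    single_b: dict
    combo: dict

    def __post_init__(self):
        if not self.combo:
            raise ScreenError(f"{self.drug_a}/{self.drug_b}: no combination cells")

    @property
    def pair(self) -> tuple[str, str]:
        return _pair_key(self.drug_a, self.drug_b)

    def swapped(self) -> "ScreenRecord":
        return ScreenRecord(cell_line=self.cell_line, drug_a=self.drug_b,
                            drug_b=self.drug_a, single_a=dict(self.single_b),
                            single_b=dict(self.single_a),
                            combo={(db, da): v for (da, db), v in self.combo.items()})


@dataclass(frozen=True)
class HsaResult:
    excess: pd.DataFrame  # rows: dose_a, cols: dose_b
    mean: float


def hsa_excess(record: ScreenRecord) -> HsaResult:
    """Per-cell HSA excess matrix and its mean over all combination cells."""
    rows = sorted({da for da, _ in record.combo})
    cols = sorted({db for _, db in record.combo})
    mat = pd.DataFrame(index=rows, columns=cols, dtype=float)
    values = []
    for (da, db), v_ab in record.combo.items():
        if da not in record.single_a:
            raise ScreenError(f"{record.pair}: missing single-agent viability for "
                              f"{record.drug_a} at dose {da}")
        if db not in record.single_b:
            raise ScreenError(f"{record.pair}: missing single-agent viability for "
                              f"{record.drug_b} at dose {db}")
        exc = v_ab - min(record.single_a[da], record.single_b[db])
        mat.loc[da, db] = exc
        values.append(exc)
    return HsaResult(excess=mat, mean=float(np.mean(values)))


@dataclass(frozen=True)
class ObservedCallSet:
    cell_line: str
    mean_excess: dict  # pair -> float
    calls: dict  # pair -> bool
    cutoff: float = DEFAULT_CUTOFF

    @property
    def n_synergies(self) -> int:
        return sum(self.calls.values())

    @property
    def n_pairs(self) -> int:
        return len(self.calls)


def binarize(mean_excess: dict, cutoff: float = DEFAULT_CUTOFF,
             cell_line: str = "") -> ObservedCallSet:
    """Observed synergy = (mean HSA excess <= cutoff); the cutoff is inclusive."""
    calls = {_pair_key(*p): (m <= cutoff) for p, m in mean_excess.items()}
    means = {_pair_key(*p): m for p, m in mean_excess.items()}
    return ObservedCallSet(cell_line=cell_line, mean_excess=means, calls=calls,
                           cutoff=cutoff)


def score_screen(records, cutoff: float = DEFAULT_CUTOFF,
                 cell_line: str | None = None) -> ObservedCallSet:
    """Binarize a list of :class:`ScreenRecord` by mean HSA excess."""
    means = {r.pair: hsa_excess(r).mean for r in records}
    cl = cell_line if cell_line is not None else (records[0].cell_line if records else "")
    return binarize(means, cutoff=cutoff, cell_line=cl)


# ---------------------------------------------------------------------------
# confusion metrics


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_evaluable(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def _ratio(num, den):
        return num / den if den else float("nan")

    @property
    def sensitivity(self):
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self):
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self):
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self):
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def balanced_accuracy(self):
        return (self.sensitivity + self.specificity) / 2

    @property
    def mcc(self):
        tp, fp, tn, fn = self.tp, self.fp, self.tn, self.fn
        den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        if den == 0:
            return float("nan")
        return (tp * tn - fp * fn) / den

    def report(self) -> dict:
        """Metrics at report precision: percentages to 1 decimal, MCC/BA to 2."""
        pct = lambda x: float("nan") if math.isnan(x) else round(100 * x, 1)
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "sensitivity_pct": pct(self.sensitivity),
            "specificity_pct": pct(self.specificity),
            "ppv_pct": pct(self.ppv),
            "npv_pct": pct(self.npv),
            "balanced_accuracy": round(self.balanced_accuracy, 2),
            "mcc": round(self.mcc, 2),
        }


def confusion(predicted: dict, observed) -> ConfusionSummary:
    """2x2 counts comparing predicted calls with observed calls.

    ``predicted`` maps pair -> bool or None (NA); NA pairs on either side
    are excluded from all counts.  Raises when the pair universes are
    disjoint.
    """
    obs_calls = observed.calls if isinstance(observed, ObservedCallSet) else dict(observed)
    pred = {_pair_key(*p): v for p, v in predicted.items()}
    obs = {_pair_key(*p): v for p, v in obs_calls.items()}
    shared = sorted(set(pred) & set(obs))
    if not shared:
        raise ScreenError("predicted and observed pair universes are disjoint")
    tp = fp = tn = fn = 0
    for p in shared:
        y_hat, y = pred[p], obs[p]
        if y_hat is None or y is None:
            continue
        if y_hat and y:
            tp += 1
        elif y_hat and not y:
            fp += 1
        elif not y_hat and y:
            fn += 1
        else:
            tn += 1
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# random baseline


@dataclass(frozen=True)
class RandomBaseline:
    reps: int
    seed: int
    n_predicted: int
    n_evaluable: int
    n_observed: int
    expected_tp: float
    expected_fp: float
    expected_tn: float
    expected_fn: float
    expected_sensitivity: float
    expected_ppv: float
    expected_npv: float
    expected_mcc: float
    analytic_tp: float
    tp_std_error: float


def random_baseline(n_predicted: int, observed, reps: int = 100_000,
                    seed: int = 0) -> RandomBaseline:
    """Expected confusion counts when the predicted synergies are drawn at random.

    Each rep draws ``n_predicted`` pairs uniformly without replacement from
    the evaluable universe of ``N`` pairs containing ``K`` observed
    synergies; the number of hits is hypergeometric, sampled with a seeded
    generator.  ``analytic_tp`` carries the closed form n*K/N.
    """
    if isinstance(observed, ObservedCallSet):
        n_total, k = observed.n_pairs, observed.n_synergies
    else:
        n_total, k = observed
    if n_predicted > n_total:
        raise ScreenError(f"cannot predict {n_predicted} of {n_total} pairs")
    rng = np.random.default_rng(seed)
    if n_predicted == 0:
        tps = np.zeros(reps)
    else:
        tps = rng.hypergeometric(k, n_total - k, n_predicted, size=reps).astype(float)
    fps = n_predicted - tps
    fns = k - tps
    tns = (n_total - k) - fps

    def safe_mean(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = num / den
        return float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else float("nan")

    with np.errstate(invalid="ignore", divide="ignore"):
        mcc_den = np.sqrt((tps + fps) * (tps + fns) * (tns + fps) * (tns + fns))
        mccs = np.where(mcc_den > 0, (tps * tns - fps * fns) / mcc_den, np.nan)
    return RandomBaseline(
        reps=reps, seed=seed, n_predicted=n_predicted, n_evaluable=n_total,
        n_observed=k,
        expected_tp=float(tps.mean()), expected_fp=float(fps.mean()),
        expected_tn=float(tns.mean()), expected_fn=float(fns.mean()),
        expected_sensitivity=safe_mean(tps, np.full(reps, k, dtype=float)) if k else float("nan"),
        expected_ppv=safe_mean(tps, np.full(reps, n_predicted, dtype=float)) if n_predicted else float("nan"),
        expected_npv=safe_mean(tns, tns + fns),
        expected_mcc=float(np.nanmean(mccs)) if np.any(np.isfinite(mccs)) else float("nan"),
        analytic_tp=n_predicted * k / n_total,
        tp_std_error=float(tps.std(ddof=1) / math.sqrt(reps)),
    )


# ---------------------------------------------------------------------------
# screen CSV IO (long format; single agents carry the other dose = 0)


def write_screen_csv(records, path=None) -> pd.DataFrame:
    rows = []
    for r in records:
        for da, v in sorted(r.single_a.items()):
            rows.append((r.cell_line, r.drug_a, r.drug_b, da, 0.0, v))
        for db, v in sorted(r.single_b.items()):
            rows.append((r.cell_line, r.drug_a, r.drug_b, 0.0, db, v))
        for (da, db), v in sorted(r.combo.items()):
            rows.append((r.cell_line, r.drug_a, r.drug_b, da, db, v))
    df = pd.DataFrame(rows, columns=["cell_line", "drug_a", "drug_b",
                                     "dose_a", "dose_b", "viability"])
    if path is not None:
        df.to_csv(path, index=False)
    return df


def read_screen_csv(source) -> list[ScreenRecord]:
    df = pd.read_csv(source)
    records = []
    for (cl, a, b), grp in df.groupby(["cell_line", "drug_a", "drug_b"], sort=True):
        single_a, single_b, combo = {}, {}, {}
        for _, row in grp.iterrows():
            da, db, v = float(row.dose_a), float(row.dose_b), float(row.viability)
            if da > 0 and db > 0:
                combo[(da, db)] = v
            elif da > 0:
                single_a[da] = v
            elif db > 0:
                single_b[db] = v
        records.append(ScreenRecord(cell_line=cl, drug_a=a, drug_b=b,
                                    single_a=single_a, single_b=single_b, combo=combo))
    return records
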