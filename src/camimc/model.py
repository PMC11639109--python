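"""Diagnostic-accuracy model and results.

:class:`DiagnosticAccuracy` is the modelling front-end: it is built
from scored observations (an ordinal 0-10 screening score, a binary
reference diagnosis, optional item flags, subgroup masks and rater
identifiers) and its :meth:`~DiagnosticAccuracy.fit` returns a
:class:`DiagnosticAccuracyResults` carrying, for each population and
cut-off, the full accuracy block — sensitivity, specificity, predictive
values (exact Clopper-Pearson CIs), likelihood ratios (log-method CIs)
and the AUROC of the dichotomised test with its DeLong CI — plus the
AUROC of the raw score and, where two index raters assessed the same
patient-days, Cohen's kappa.

Example
-------
>>> from camimc import simulate_cohort, score_records, DiagnosticAccuracy
>>> sim = simulate_cohort(seed=1)
>>> scored = score_records(sim.assessments, sim.baseline)
>>> res = DiagnosticAccuracy.from_dataframe(scored.data).fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import decimal
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import accuracy as acc
from .instrument import DEFAULT_CUTOFF

__all__ = [
    "DiagnosticAccuracy",
    "DiagnosticAccuracyResults",
    "CutoffBlock",
    "PopulationResults",
    "evaluate",
    "round_half_up",
]

logger = logging.getLogger("camimc")

_ITEM_LABELS = {
    "fluctuation": "Acute change/fluctuation",
    "consciousness": "Altered level of consciousness",
    "inattention": "Inattention",
    "disorientation": "Disorientation",
}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention; internal math is
    kept at full precision)."""
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return x
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class CutoffBlock:
    """Accuracy estimates for one dichotomisation of one population."""

    label: str
    counts: acc.ConfusionCounts
    estimates: acc.AccuracyEstimates
    ratios: Optional[acc.LikelihoodRatios]
    auroc: Optional[acc.AurocEstimate]

    def row(self) -> dict:
        """Flat dict of point estimates and CI bounds (full precision)."""
        def p(est):
            return (est.point, est.ci_low, est.ci_high) if est else (None,) * 3

        out = {"label": self.label, "n": self.counts.n,
               "tp": self.counts.tp, "fp": self.counts.fp,
               "fn": self.counts.fn, "tn": self.counts.tn}
        for name, est in (("sens", self.estimates.sensitivity),
                          ("spec", self.estimates.specificity),
                          ("ppv", self.estimates.ppv),
                          ("npv", self.estimates.npv)):
            out[name], out[f"{name}_low"], out[f"{name}_high"] = p(est)
        for name, est in (("lr_pos", self.ratios.lr_pos if self.ratios else None),
                          ("lr_neg", self.ratios.lr_neg if self.ratios else None)):
            out[name], out[f"{name}_low"], out[f"{name}_high"] = p(est)
        if self.auroc is not None:
            out["auroc"] = self.auroc.auc
            out["auroc_low"], out["auroc_high"] = self.auroc.ci_low, self.auroc.ci_high
        else:
            out["auroc"] = out["auroc_low"] = out["auroc_high"] = None
        return out


@dataclass(frozen=True)
class PopulationResults:
    """All blocks for one analysis population."""

    name: str
    n_observations: int
    n_positive: int
    cutoff_blocks: tuple          # one CutoffBlock per cut-off
    item_blocks: tuple            # one CutoffBlock per item flag
    raw_auroc: Optional[acc.AurocEstimate]
    roc: Optional[acc.RocCurve]


@dataclass(frozen=True)
class DiagnosticAccuracyResults:
    """Fitted accuracy report.

    Attributes
    ----------
    populations : tuple of PopulationResults
        ``all`` first, then each subgroup with both reference classes
        present.
    kappa : KappaEstimate or None
        Interrater reliability of test positivity at the primary
        cut-off over patient-days assessed by both index raters.
    youden_cutoff : int
        Cut-off maximising the Youden index on the full population.
    """

    model: "DiagnosticAccuracy"
    populations: tuple
    kappa: Optional[acc.KappaEstimate]
    n_rater_pairs: int
    cutoffs: tuple
    alpha: float

    def population(self, name: str) -> PopulationResults:
        for pop in self.populations:
            if pop.name == name:
                return pop
        raise KeyError(f"no population named {name!r}")

    @property
    def youden_cutoff(self) -> int:
        blocks = self.population("all").cutoff_blocks
        triples = [
            (int(b.label), b.estimates.sensitivity.point,
             b.estimates.specificity.point)
            for b in blocks
            if b.estimates.sensitivity and b.estimates.specificity
        ]
        return acc.youden_optimal(triples)

    # -- tables -------------------------------------------------------------

    def cutoff_table(self, rounded: bool = False) -> pd.DataFrame:
        """Per-population, per-cut-off accuracy table (Table-2 layout)."""
        rows = []
        for pop in self.populations:
            for block in pop.cutoff_blocks:
                row = {"population": pop.name, "cutoff": int(block.label),
                       **block.row()}
                row.pop("label")
                rows.append(row)
        df = pd.DataFrame(rows)
        return self._round(df) if rounded else df

    def item_table(self, rounded: bool = False) -> pd.DataFrame:
        """Per-population, per-item accuracy table (Table-3 layout)."""
        rows = []
        for pop in self.populations:
            for block in pop.item_blocks:
                row = {"population": pop.name, "item": block.label, **block.row()}
                row.pop("label")
                rows.append(row)
        df = pd.DataFrame(rows)
        return self._round(df) if rounded else df

    def roc_table(self) -> pd.DataFrame:
        """ROC coordinates of the raw score for every population."""
        frames = []
        for pop in self.populations:
            if pop.roc is None:
                continue
            c, s, f = pop.roc.to_arrays()
            frames.append(pd.DataFrame({
                "population": pop.name, "cutoff": c,
                "sensitivity": s, "fpr": f,
            }))
        return pd.concat(frames, ignore_index=True)

    @staticmethod
    def _round(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col in out.columns:
            if out[col].dtype.kind == "f":
                out[col] = out[col].map(lambda v: round_half_up(v, 2))
        return out

    def to_dict(self) -> dict:
        """JSON-serialisable report."""
        def clean(v):
            if isinstance(v, float) and not math.isfinite(v):
                return repr(v)  # 'inf' / 'nan' survive JSON round-trips as strings
            return v

        out = {
            "alpha": self.alpha,
            "cutoffs": list(self.cutoffs),
            "youden_cutoff": self.youden_cutoff,
            "populations": {},
            "kappa": None,
            "n_rater_pairs": self.n_rater_pairs,
        }
        for pop in self.populations:
            out["populations"][pop.name] = {
                "n_observations": pop.n_observations,
                "n_positive": pop.n_positive,
                "cutoffs": {b.label: {k: clean(v) for k, v in b.row().items()}
                            for b in pop.cutoff_blocks},
                "items": {b.label: {k: clean(v) for k, v in b.row().items()}
                          for b in pop.item_blocks},
                "raw_auroc": (
                    None if pop.raw_auroc is None else {
                        "auc": pop.raw_auroc.auc,
                        "se": clean(pop.raw_auroc.se),
                        "ci_low": pop.raw_auroc.ci_low,
                        "ci_high": pop.raw_auroc.ci_high,
                    }
                ),
            }
        if self.kappa is not None:
            out["kappa"] = {
                "kappa": clean(self.kappa.kappa),
                "se": clean(self.kappa.se),
                "ci_low": clean(self.kappa.ci_low),
                "ci_high": clean(self.kappa.ci_high),
                "n_pairs": self.kappa.n,
                "defined": self.kappa.defined,
            }
        return out

    def summary(self) -> str:
        """Aligned-text summary of the fitted report."""
        lines = ["CAM-IMC diagnostic accuracy", "=" * 74]
        for pop in self.populations:
            lines.append(
                f"\nPopulation: {pop.name}  "
                f"(n={pop.n_observations}, reference-positive={pop.n_positive})"
            )
            header = (f"{'cutoff':>6} {'sens':>12} {'spec':>12} {'ppv':>12} "
                      f"{'npv':>12} {'LR+':>8} {'LR-':>6} {'AUROC':>12}")
            lines.append(header)

            def fmt(est, w=12):
                if est is None:
                    return " " * w
                return (f"{round_half_up(est.point):.2f}"
                        f"({round_half_up(est.ci_low):.2f}-"
                        f"{round_half_up(est.ci_high):.2f})").rjust(w)

            for block in pop.cutoff_blocks + pop.item_blocks:
                e, r = block.estimates, block.ratios
                lrp = (f"{round_half_up(r.lr_pos.point):.2f}" if r and
                       math.isfinite(r.lr_pos.point) else "Inf") if r else ""
                lrn = (f"{round_half_up(r.lr_neg.point):.2f}" if r else "")
                auc = ""
                if block.auroc is not None:
                    auc = (f"{round_half_up(block.auroc.auc):.2f}"
                           f"({round_half_up(block.auroc.ci_low):.2f}-"
                           f"{round_half_up(block.auroc.ci_high):.2f})")
                lines.append(
                    f"{block.label:>6} {fmt(e.sensitivity)} {fmt(e.specificity)} "
                    f"{fmt(e.ppv)} {fmt(e.npv)} {lrp:>8} {lrn:>6} {auc:>12}"
                )
            if pop.raw_auroc is not None:
                lines.append(
                    f"raw-score AUROC: {round_half_up(pop.raw_auroc.auc):.2f} "
                    f"({round_half_up(pop.raw_auroc.ci_low):.2f}-"
                    f"{round_half_up(pop.raw_auroc.ci_high):.2f})"
                )
        lines.append(f"\nYouden-optimal cut-off: {self.youden_cutoff}")
        if self.kappa is not None:
            lines.append(
                f"Interrater kappa ({self.n_rater_pairs} paired assessments): "
                f"{round_half_up(self.kappa.kappa):.2f} "
                f"({round_half_up(self.kappa.ci_low):.2f}-"
                f"{round_half_up(self.kappa.ci_high):.2f})"
            )
        return "\n".join(lines)


class DiagnosticAccuracy:
    """Diagnostic accuracy of an ordinal screening score against a
    binary reference standard.

    Parameters
    ----------
    score : array-like of int
        The 0-10 CAM-IMC total per observation.
    reference : array-like of bool
        Reference-standard delirium diagnosis per observation.
    items : mapping of str to array-like, optional
        Item-level dichotomisations; ``None`` entries (missing
        responses) are dropped pairwise per item.
    groups : mapping of str to boolean array-like, optional
        Subgroup membership masks; observations with missing membership
        (NA) are excluded from that subgroup only.
    patient, day, rater : array-like, optional
        Identifiers used to pair the two index raters' same-day
        assessments for the interrater-reliability estimate.
    alpha : float
        Two-sided error level for every confidence interval.

    Notes
    -----
    The unit of analysis is the observation; within-patient clustering
    is ignored, so confidence intervals are anti-conservative when
    patients contribute several observations.
    """

    def __init__(self, score, reference, *, items=None, groups=None,
                 patient=None, day=None, rater=None, alpha: float = 0.05):
        self.score = np.asarray(score, dtype=int)
        self.reference = np.asarray(reference, dtype=bool)
        if self.score.shape != self.reference.shape or self.score.ndim != 1:
            raise ValueError("score and reference must be equal-length 1-d arrays")
        if self.score.size == 0:
            raise ValueError("no observations")
        if not (0.0 < alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {alpha}")
        self.items = {k: np.asarray(v, dtype=object) for k, v in (items or {}).items()}
        self.groups = {k: v for k, v in (groups or {}).items()}
        self.patient = None if patient is None else np.asarray(patient)
        self.day = None if day is None else np.asarray(day)
        self.rater = None if rater is None else np.asarray(rater)
        self.alpha = alpha
        logger.debug(
            "observation-level analysis: CIs ignore within-patient clustering"
        )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        score: str = "camimc_total",
        reference: str = "reference_delirium",
        alpha: float = 0.05,
    ) -> "DiagnosticAccuracy":
        """Build the model from a scored-records table.

        Columns named ``flag_<item>`` become item dichotomisations and
        columns named ``subgroup_<name>`` become subgroup masks;
        ``patient_id``/``day``/``rater_id``, if present, enable the
        interrater-reliability estimate.
        """
        items = {
            c.removeprefix("flag_"): data[c].to_numpy()
            for c in data.columns if c.startswith("flag_")
        }
        groups = {
            c.removeprefix("subgroup_"): data[c]
            for c in data.columns if c.startswith("subgroup_")
        }
        ids = {
            dest: data[col].to_numpy()
            for dest, col in (("patient", "patient_id"), ("day", "day"),
                              ("rater", "rater_id"))
            if col in data.columns
        }
        return cls(
            data[score].to_numpy(),
            data[reference].to_numpy(dtype=bool),
            items=items, groups=groups, alpha=alpha, **ids,
        )

    # -- fitting --------------------------------------------------------------

    def _block(self, positive: np.ndarray, reference: np.ndarray,
               label: str) -> CutoffBlock:
        counts = acc.build_confusion(positive, reference)
        estimates = acc.accuracy_estimates(counts, self.alpha)
        ratios = auc_est = None
        if counts.n_positive > 0 and counts.n_negative > 0:
            ratios = acc.likelihood_ratios(counts, self.alpha)
            if counts.n_positive >= 2 and counts.n_negative >= 2:
                auc_est = acc.delong_ci(
                    positive.astype(int), reference, self.alpha
                )
        return CutoffBlock(label=label, counts=counts, estimates=estimates,
                           ratios=ratios, auroc=auc_est)

    def _population(self, name: str, mask: np.ndarray,
                    cutoffs: Sequence[int]) -> Optional[PopulationResults]:
        score = self.score[mask]
        ref = self.reference[mask]
        if score.size == 0:
            warnings.warn(f"population {name!r} is empty; section omitted")
            return None
        single_class = ref.all() or not ref.any()
        if single_class:
            warnings.warn(
                f"population {name!r} has a single reference class; "
                "ROC-based estimates are undefined"
            )
        cutoff_blocks = [
            self._block(score >= c, ref, str(c)) for c in cutoffs
        ]
        item_blocks = []
        for item, flags in self.items.items():
            f = flags[mask]
            known = np.array([v is not None and v == v for v in f])
            if known.sum() == 0:
                continue
            item_blocks.append(self._block(
                np.asarray(f[known], dtype=bool), ref[known],
                _ITEM_LABELS.get(item, item),
            ))
        raw_auc = roc = None
        if not single_class:
            roc = acc.roc_points(score, ref)
            if ref.sum() >= 2 and (~ref).sum() >= 2:
                raw_auc = acc.delong_ci(score, ref, self.alpha)
        return PopulationResults(
            name=name,
            n_observations=int(score.size),
            n_positive=int(ref.sum()),
            cutoff_blocks=tuple(cutoff_blocks),
            item_blocks=tuple(item_blocks),
            raw_auroc=raw_auc,
            roc=roc,
        )

    def _interrater(self, cutoff: int):
        """Pair the two index raters' same-day positivity."""
        if self.patient is None or self.day is None or self.rater is None:
            return None, 0
        df = pd.DataFrame({
            "patient": self.patient, "day": self.day, "rater": self.rater,
            "positive": self.score >= cutoff,
        })
        wide = df.pivot_table(index=["patient", "day"], columns="rater",
                              values="positive", aggfunc="first")
        wide = wide.dropna()
        if wide.shape[1] != 2 or len(wide) < 2:
            return None, int(len(wide))
        a, b = (wide.iloc[:, j].to_numpy(dtype=bool) for j in (0, 1))
        return acc.cohen_kappa(a, b, self.alpha), int(len(wide))

    def fit(self, cutoffs: Sequence[int] = (3, 4, 5),
            primary_cutoff: int = DEFAULT_CUTOFF) -> DiagnosticAccuracyResults:
        """Estimate the full accuracy report.

        Parameters
        ----------
        cutoffs : sequence of int
            Candidate positivity cut-offs on the 0-10 total.
        primary_cutoff : int
            Cut-off used for the interrater-reliability pairing.
        """
        if any(not (0 <= c <= 10) for c in cutoffs):
            raise ValueError(f"cutoffs must be within 0-10, got {list(cutoffs)}")
        populations = []
        pop_all = self._population("all", np.ones_like(self.reference), cutoffs)
        if pop_all is not None:
            populations.append(pop_all)
        for name, membership in self.groups.items():
            m = pd.array(membership)
            mask = (m.fillna(False) if hasattr(m, "fillna") else m).to_numpy(
                dtype=bool
            )
            pop = self._population(name, mask, cutoffs)
            if pop is not None:
                populations.append(pop)
        kappa, n_pairs = self._interrater(primary_cutoff)
        return DiagnosticAccuracyResults(
            model=self,
            populations=tuple(populations),
            kappa=kappa,
            n_rater_pairs=n_pairs,
            cutoffs=tuple(int(c) for c in cutoffs),
            alpha=self.alpha,
        )


def evaluate(
    data: pd.DataFrame,
    cutoffs: Sequence[int] = (3, 4, 5),
    alpha: float = 0.05,
) -> DiagnosticAccuracyResults:
    """Fit the accuracy report on a scored-records table.

    Convenience wrapper equivalent to
    ``DiagnosticAccuracy.from_dataframe(data, alpha=alpha).fit(cutoffs)``.
    """
    return DiagnosticAccuracy.from_dataframe(data, alpha=alpha).fit(cutoffs)
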