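"""End-to-end online grading: image -> predicted mass -> grade -> routing.

Mirrors the integrated machine: the CNN predicts each cucumber's mass from
its top-view image, the mass-to-grade rule converts predictions to grade
commands, and the grade stream drives the simulated grading line. Misgrades
can therefore arise from two mechanisms — prediction error pushing a mass
across a grade boundary, and sensor faults desynchronizing the tray shift
register — and the report separates regression quality (RMSE, MAPE, R^2)
from routing quality (the grading-efficiency table).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grader_sim import SimConfig, SimResult, run_simulation
from .grading_rules import GradingOutcome, assign_grade
from .model import MassPredictor, predict_mass
from .training_eval import EvaluationSet, ImageSet, MetricsReport, mape, rmse

__all__ = [
    "OnlineGradingReport",
    "run_online_grading",
    "coefficient_of_determination",
]


@dataclass
class OnlineGradingReport:
    true_mass: np.ndarray
    predicted_mass: np.ndarray
    true_grade: list[int]
    predicted_grade: list[int]
    routed_grade: list[int]
    metrics: MetricsReport
    r2: float
    outcome: GradingOutcome
    grading_speed_items_per_min: float
    sim: SimResult

    def __len__(self) -> int:
        return len(self.true_mass)

    def to_dict(self) -> dict:
        return {
            "n": len(self),
            "rmse_g": self.metrics.rmse,
            "mape_pct": self.metrics.mape,
            "r2": self.r2,
            "eta0_pct": self.outcome.eta0,
            "t_n": self.outcome.t_n,
            "t_m": self.outcome.t_m,
            "grading_speed_items_per_min": self.grading_speed_items_per_min,
            "outcome_rows": self.outcome.as_rows(),
        }


def coefficient_of_determination(ev: EvaluationSet) -> float:
    """R^2 = 1 - SS_res / SS_tot between predicted and actual masses."""
    if ev.n < 2:
        raise ValueError("need at least 2 pairs for R^2")
    ss_tot = float(np.sum((ev.actual - ev.actual.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("actual masses have zero variance; R^2 undefined")
    ss_res = float(np.sum((ev.predicted - ev.actual) ** 2))
    return 1.0 - ss_res / ss_tot


def run_online_grading(
    model: MassPredictor | None,
    test_set: ImageSet,
    sim_config: SimConfig | None = None,
    batch: int = 32,
    predicted_masses: np.ndarray | None = None,
) -> OnlineGradingReport:
    """Grade a sequence of imaged cucumbers end to end on the simulated line.

    ``predicted_masses`` substitutes a precomputed prediction stream for the
    model (useful for what-if analyses such as an oracle or a biased
    predictor); otherwise the model predicts from the images.
    """
    if len(test_set) == 0:
        raise ValueError("test set is empty")
    if predicted_masses is not None:
        predicted = np.asarray(predicted_masses, dtype=float).reshape(-1)
        if len(predicted) != len(test_set):
            raise ValueError("predicted_masses length must match the test set")
    else:
        if model is None:
            raise ValueError("provide a model or predicted_masses")
        preds = []
        for start in range(0, len(test_set), batch):
            preds.append(
                np.atleast_1d(
                    predict_mass(model, test_set.images[start : start + batch])
                )
            )
        predicted = np.concatenate(preds)

    cfg = sim_config or SimConfig()
    cfg = replace(cfg, n_trays=len(test_set))
    true_grades = [assign_grade(m, cfg.thresholds) for m in test_set.masses]
    pred_grades = [assign_grade(max(m, 1e-9), cfg.thresholds) for m in predicted]
    sim = run_simulation(
        cfg,
        masses=test_set.masses,
        true_grades=true_grades,
        detected_grades=pred_grades,
    )
    routed = [t.routed_grade for t in sim.trays]

    ev = EvaluationSet(predicted, test_set.masses)
    metrics = MetricsReport(rmse=rmse(ev), mape=mape(ev), n=ev.n)
    items_per_min = 60.0 / cfg.tray_interval_s
    return OnlineGradingReport(
        true_mass=np.asarray(test_set.masses, dtype=float),
        predicted_mass=predicted,
        true_grade=true_grades,
        predicted_grade=pred_grades,
        routed_grade=routed,
        metrics=metrics,
        r2=coefficient_of_determination(ev),
        outcome=sim.outcome,
        grading_speed_items_per_min=items_per_min,
        sim=sim,
    )
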