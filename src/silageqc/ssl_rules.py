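"""Teacher-student semi-supervised update rules, plus a desk-scale toy loop.

The update rules are those of confidence-gated pseudo-labelling with an
exponential-moving-average teacher: the teacher predicts on weakly perturbed
unlabelled inputs, predictions above a confidence threshold become training
targets for the student on strongly perturbed inputs, the student minimises
``supervised_loss + unsup_weight * unsupervised_loss``, and the teacher's
parameters track the student's with EMA decay alpha (default 0.9996).
Training runs ``total_iters`` iterations (default 50,000) of which the first
``burn_in_iters`` (default 10,000) are supervised-only; after burn-in the
model is duplicated into teacher and student.

``run_toy_ssl`` executes that loop literally on a deliberately tiny problem:
a one-parameter-family logistic "detector" separating two 1-D Gaussian
clusters.  Each unlabelled scene is a handful of candidate particles;
teacher scores above the confidence threshold become positive pseudo-labels
and everything below becomes background, exactly as sub-threshold detections
do in detection pseudo-labelling.  A low threshold therefore injects
false-positive labels and a high one false negatives — the trade-off the
confidence-threshold sweep probes.  The claim tested is the mechanism, never
any absolute detection-metric value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import AnnotationSet

__all__ = [
    "SSLConfig",
    "ToyProblem",
    "ToyRunReport",
    "filter_pseudo_labels",
    "ema_update",
    "combined_loss",
    "run_toy_ssl",
    "run_supervised_baseline",
    "ssl_sweep",
]


@dataclass(frozen=True)
class SSLConfig:
    bbox_confidence_threshold: float = 0.5
    n_unsup_images: int = 4
    unsup_weight: float = 4.0
    ema_alpha: float = 0.9996
    burn_in_iters: int = 10_000
    total_iters: int = 50_000
    seed: int = 0
    loss_ceiling: float = 1e6  # beyond this a run is reported as diverged

    def __post_init__(self) -> None:
        if not 0.0 < self.bbox_confidence_threshold <= 1.0:
            raise ValueError("confidence threshold must lie in (0, 1]")
        if not 0.0 <= self.ema_alpha <= 1.0:
            raise ValueError("ema_alpha must lie in [0, 1]")
        if self.n_unsup_images < 1:
            raise ValueError("n_unsup_images must be positive")
        if self.unsup_weight < 0:
            raise ValueError("unsup_weight must be non-negative")

    def scaled_down(
        self, burn_in: int = 60, total: int = 240, ema_alpha: float = 0.95
    ) -> "SSLConfig":
        """Toy-scale copy of the full-scale defaults.

        Iteration counts shrink to a desk-runnable budget and the EMA decay
        shrinks with them: at full scale the teacher's averaging timescale
        1/(1-alpha) = 2500 iterations is a small fraction of the 40,000
        post-burn-in iterations, and alpha = 0.95 (timescale 20) preserves
        that ratio for a 180-iteration toy run.  Every rule parameter that is
        scale-free (threshold, weight, image count) is unchanged.
        """
        return replace(
            self, burn_in_iters=burn_in, total_iters=total, ema_alpha=ema_alpha
        )


def filter_pseudo_labels(det: AnnotationSet, threshold: float) -> AnnotationSet:
    """Keep detections with score >= threshold and strip the scores, so the
    survivors can serve the student as ground truth."""
    kept = [
        replace(i, score=None)
        for i in det.instances
        if i.score is not None and i.score >= threshold
    ]
    return AnnotationSet(
        source_id=f"{det.source_id}+pseudo",
        images=dict(det.images),
        instances=kept,
    )


def ema_update(teacher: np.ndarray, student: np.ndarray, alpha: float) -> np.ndarray:
    """Elementwise ``alpha * teacher + (1 - alpha) * student``."""
    teacher = np.asarray(teacher, dtype=float)
    student = np.asarray(student, dtype=float)
    if teacher.shape != student.shape:
        raise ValueError(
            f"teacher and student shapes differ: {teacher.shape} vs {student.shape}"
        )
    return alpha * teacher + (1.0 - alpha) * student


def combined_loss(sup_loss: float, unsup_loss: float, unsup_weight: float) -> float:
    """Total training loss: ``sup_loss + unsup_weight * unsup_loss``."""
    if sup_loss < 0 or unsup_loss < 0:
        raise ValueError("losses must be non-negative")
    return sup_loss + unsup_weight * unsup_loss


# ---------------------------------------------------------------------------
# toy problem


@dataclass(frozen=True)
class ToyProblem:
    """Two 1-D Gaussian clusters of candidate particles; positives sit at
    ``pos_mean``, background at ``neg_mean``.  The detector is a logistic
    scorer sigmoid(w1 * x + w0); weak/strong augmentation adds small/large
    Gaussian input noise."""

    pos_mean: float = 1.0
    neg_mean: float = -1.0
    cluster_sd: float = 0.35
    n_labeled: int = 8
    items_per_scene: int = 12
    weak_aug_sd: float = 0.05
    strong_aug_sd: float = 0.4
    lr: float = 0.3
    test_n: int = 2000
    eval_every: int = 20


@dataclass(frozen=True)
class ToyRunReport:
    teacher_errors: np.ndarray  # held-out error per evaluation point
    student_errors: np.ndarray
    eval_iters: np.ndarray
    final_teacher_error: float
    final_student_error: float
    teacher_params: np.ndarray
    student_params: np.ndarray
    diverged: bool = False


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -40.0, 40.0)))


def _logistic_grad(w: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mean logistic-loss gradient for scores sigmoid(w1 * x + w0)."""
    p = _sigmoid(w[1] * x + w[0])
    err = p - y
    return np.array([err.mean(), (err * x).mean()])


def _logistic_loss(w: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    p = _sigmoid(w[1] * x + w[0])
    eps = 1e-12
    return float(-(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)).mean())


def _draw_mixture(
    rng: np.random.Generator, problem: ToyProblem, n: int
) -> tuple[np.ndarray, np.ndarray]:
    y = rng.integers(0, 2, size=n).astype(float)
    x = np.where(y == 1, problem.pos_mean, problem.neg_mean) + (
        problem.cluster_sd * rng.standard_normal(n)
    )
    return x, y


def _error_rate(w: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    pred = (_sigmoid(w[1] * x + w[0]) >= 0.5).astype(float)
    return float(np.mean(pred != y))


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """(data stream, unlabelled/augmentation stream) — separated so that a
    supervised-only run never consumes the unlabelled stream."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(4,))
    data_ss, unsup_ss = ss.spawn(2)
    return np.random.default_rng(data_ss), np.random.default_rng(unsup_ss)


def _burn_in(
    problem: ToyProblem, rng_data: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    x_lab, y_lab = _draw_mixture(rng_data, problem, problem.n_labeled)
    x_test, y_test = _draw_mixture(rng_data, problem, problem.test_n)
    w = np.array([0.0, 1.0])
    return w, x_lab, y_lab, x_test, y_test


def run_supervised_baseline(problem: ToyProblem, cfg: SSLConfig) -> ToyRunReport:
    """Supervised-only training for ``total_iters`` iterations: the reference
    every teacher-student run is compared against.  Uses the same data stream
    as :func:`run_toy_ssl` with the same seed, so the labelled and held-out
    sets are identical."""
    rng_data, _ = _streams(cfg.seed)
    w, x_lab, y_lab, x_test, y_test = _burn_in(problem, rng_data)
    eval_iters, errors = [], []
    for it in range(cfg.total_iters):
        w = w - problem.lr * _logistic_grad(w, x_lab, y_lab)
        if (it + 1) % problem.eval_every == 0 or it + 1 == cfg.total_iters:
            eval_iters.append(it + 1)
            errors.append(_error_rate(w, x_test, y_test))
    err = np.array(errors)
    return ToyRunReport(
        teacher_errors=err,
        student_errors=err,
        eval_iters=np.array(eval_iters),
        final_teacher_error=float(err[-1]),
        final_student_error=float(err[-1]),
        teacher_params=w.copy(),
        student_params=w.copy(),
    )


def run_toy_ssl(problem: ToyProblem, cfg: SSLConfig) -> ToyRunReport:
    """Run the teacher-student loop literally, at toy scale.

    Burn-in trains on the labelled set only; the model is then duplicated
    into teacher and student.  Each iteration draws ``n_unsup_images``
    scenes, the teacher pseudo-labels their weakly perturbed items (score
    above the confidence threshold => positive, below => background), the
    student takes one gradient step on the combined loss evaluated on the
    strongly perturbed items, and the teacher is refined by EMA.
    Deterministic given ``cfg.seed``; a run whose loss exceeds the configured
    ceiling is reported as diverged, not raised.
    """
    if cfg.burn_in_iters >= cfg.total_iters:
        raise ValueError(
            f"burn_in_iters ({cfg.burn_in_iters}) must be below total_iters "
            f"({cfg.total_iters})"
        )
    rng_data, rng_unsup = _streams(cfg.seed)
    w, x_lab, y_lab, x_test, y_test = _burn_in(problem, rng_data)

    eval_iters: list[int] = []
    t_err: list[float] = []
    s_err: list[float] = []
    diverged = False

    for it in range(cfg.burn_in_iters):
        w = w - problem.lr * _logistic_grad(w, x_lab, y_lab)

    teacher = w.copy()
    student = w.copy()
    n_items = cfg.n_unsup_images * problem.items_per_scene
    for it in range(cfg.burn_in_iters, cfg.total_iters):
        x_unsup, _ = _draw_mixture(rng_unsup, problem, n_items)
        x_weak = x_unsup + problem.weak_aug_sd * rng_unsup.standard_normal(n_items)
        scores = _sigmoid(teacher[1] * x_weak + teacher[0])
        pseudo_y = (scores >= cfg.bbox_confidence_threshold).astype(float)
        x_strong = x_unsup + problem.strong_aug_sd * rng_unsup.standard_normal(n_items)

        sup_grad = _logistic_grad(student, x_lab, y_lab)
        unsup_grad = _logistic_grad(student, x_strong, pseudo_y)
        student = student - problem.lr * (sup_grad + cfg.unsup_weight * unsup_grad)
        teacher = ema_update(teacher, student, cfg.ema_alpha)

        loss = combined_loss(
            _logistic_loss(student, x_lab, y_lab),
            _logistic_loss(student, x_strong, pseudo_y),
            cfg.unsup_weight,
        )
        if not math.isfinite(loss) or loss > cfg.loss_ceiling:
            diverged = True
            break
        if (it + 1) % problem.eval_every == 0 or it + 1 == cfg.total_iters:
            eval_iters.append(it + 1)
            t_err.append(_error_rate(teacher, x_test, y_test))
            s_err.append(_error_rate(student, x_test, y_test))

    if not eval_iters:  # diverged before the first evaluation point
        eval_iters = [cfg.burn_in_iters]
        t_err = [_error_rate(teacher, x_test, y_test)]
        s_err = [_error_rate(student, x_test, y_test)]
    return ToyRunReport(
        teacher_errors=np.array(t_err),
        student_errors=np.array(s_err),
        eval_iters=np.array(eval_iters),
        final_teacher_error=float(t_err[-1]),
        final_student_error=float(s_err[-1]),
        teacher_params=teacher.copy(),
        student_params=student.copy(),
        diverged=diverged,
    )


SWEEP_THRESHOLDS = (0.1, 0.3, 0.5, 0.7)
SWEEP_N_UNSUP = (1, 4)
SWEEP_WEIGHTS = (0.5, 4.0)


def ssl_sweep(
    problem: ToyProblem,
    base_cfg: SSLConfig,
    thresholds=SWEEP_THRESHOLDS,
    n_unsup=SWEEP_N_UNSUP,
    weights=SWEEP_WEIGHTS,
):
    """Run the full confidence-threshold x images x weight grid at toy scale.

    Returns a list of row dicts (one per configuration plus the supervised
    baseline) in the layout of the hyper-parameter sweep tables: the three
    swept parameters and the final teacher/student held-out errors, with
    diverged runs flagged.
    """
    rows = []
    baseline = run_supervised_baseline(problem, base_cfg)
    rows.append(
        {
            "bbox_thresh": None,
            "n_unsup_images": None,
            "unsup_weight": None,
            "teacher_error": baseline.final_teacher_error,
            "student_error": baseline.final_student_error,
            "diverged": False,
            "run_id": "baseline",
        }
    )
    for thr in thresholds:
        for n in n_unsup:
            for wgt in weights:
                cfg = replace(
                    base_cfg,
                    bbox_confidence_threshold=thr,
                    n_unsup_images=n,
                    unsup_weight=wgt,
                )
                rep = run_toy_ssl(problem, cfg)
                rows.append(
                    {
                        "bbox_thresh": thr,
                        "n_unsup_images": n,
                        "unsup_weight": wgt,
                        "teacher_error": (
                            None if rep.diverged else rep.final_teacher_error
                        ),
                        "student_error": (
                            None if rep.diverged else rep.final_student_error
                        ),
                        "diverged": rep.diverged,
                        "run_id": f"thr{thr}-n{n}-w{wgt}",
                    }
                )
    return rows
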