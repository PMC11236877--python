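"""Self-contained synthetic benchmarks exercising the full pipeline.

These routines generate their own inputs (stated-world defaults), run the
analysis chains end-to-end, and return measured quantities; they back both
the acceptance test suite and the standalone acceptance script.
"""

from __future__ import annotations

import numpy as np

from . import stimulus as st
from . import synth
from .classify import evaluate, train_classifier, train_from_waveforms
from .features import extract_feature_matrix
from .pipeline import run_ffvep_analysis

__all__ = [
    "ffvep_parameter_recovery",
    "ffvep_abnormal_detection_rate",
    "defect_classification_benchmark",
]


def _short_ffvep_schedule(seed: int):
    # 30 trials/eye in 2 segments: enough trials for stable averages at a
    # fraction of the default simulation cost
    return st.build_ffvep_schedule(trials_per_eye=30, segments=2, seed=seed)


def ffvep_parameter_recovery(n_subjects: int = 20, seed: int = 0) -> dict:
    """Simulate subjects with programmed P100 peak times spread over
    90–125 ms, run the full-field pipeline, and regress estimated on
    configured peak time.  Returns the regression slope and the paired
    values."""
    rng = np.random.default_rng(seed)
    configured = np.linspace(90.0, 125.0, n_subjects)
    estimated = []
    for i, pt in enumerate(configured):
        sched = _short_ffvep_schedule(seed=int(rng.integers(1 << 30)))
        cfg = synth.SimulationConfig(
            seed=int(rng.integers(1 << 30)),
            p100_peak_ms={"L": float(pt), "R": float(pt)},
        )
        rec = synth.simulate_ffvep_recording(sched, cfg)
        res = run_ffvep_analysis(rec)
        m = res.measures[("CA", "L")]
        estimated.append(m.peak_time_ms if m.present else np.nan)
    estimated = np.asarray(estimated)
    ok = np.isfinite(estimated)
    slope, intercept = np.polyfit(configured[ok], estimated[ok], 1)
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "configured": configured,
        "estimated": estimated,
    }


def ffvep_abnormal_detection_rate(
    n_runs: int = 50, seed: int = 0, n_std: float = 4.0
) -> float:
    """Fraction of seeded runs in which an eye programmed at the normative
    mean + ``n_std`` standard deviations of central peak time is classified
    abnormal."""
    from .ffvep import default_normative_stats

    norms = default_normative_stats()
    mean = float(norms.table.loc["CA_peak_time", "mean"])
    std = float(norms.table.loc["CA_peak_time", "std"])
    target = mean + n_std * std
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        sched = _short_ffvep_schedule(seed=int(rng.integers(1 << 30)))
        cfg = synth.SimulationConfig(
            seed=int(rng.integers(1 << 30)),
            p100_peak_ms={"L": target, "R": 100.0},
        )
        rec = synth.simulate_ffvep_recording(sched, cfg)
        res = run_ffvep_analysis(rec, norms=norms)
        if res.report.classes.get("CA_peak_time_L") == "abnormal":
            hits += 1
    return hits / n_runs


def defect_classification_benchmark(
    seed: int = 0,
    n_train_tests: int = 7,
    n_eval_tests: int = 16,
    augment_target: int = 8192,
    cv_folds: int = 5,
    ablations: bool = False,
) -> dict:
    """Train on ring-mask artificial-defect simulations, evaluate on a
    disjoint simulated set.

    The training and evaluation sets use disjoint simulation seeds (distinct
    noise realizations and defect layouts); ``augment_target`` defaults to a
    scaled-down 8192 (the production default is 65,536) to keep the benchmark
    inside a desktop CPU budget.  With ``ablations`` the benchmark also fits
    models without augmentation and without the 7 canonical time-series
    features.
    """
    mseqs = st.generate_msequences(seed=1)
    train = synth.make_artificial_defect_dataset(n_tests=n_train_tests, seed=seed * 2 + 11, mseqs=mseqs)
    eval_ = synth.make_artificial_defect_dataset(n_tests=n_eval_tests, seed=seed * 2 + 1000, mseqs=mseqs)
    model = train_from_waveforms(
        train.responses, train.labels, augment_target=augment_target, seed=seed, cv_folds=cv_folds
    )
    Fe = extract_feature_matrix(eval_.responses, model.reference)
    metrics = evaluate(model, Fe, eval_.labels)
    out = {
        "metrics": metrics,
        "cv_scores": model.cv_scores,
        "n_train": len(train),
        "n_eval": len(eval_),
        "model": model,
    }
    if ablations:
        from .classify import augment_dataset

        # without augmentation: fit on the raw labeled responses
        m_noaug = train_from_waveforms(train.responses, train.labels, augment_target=0, seed=seed)
        F_noaug = extract_feature_matrix(eval_.responses, m_noaug.reference)
        out["metrics_no_augmentation"] = evaluate(m_noaug, F_noaug, eval_.labels)
        # without the 7 canonical time-series features: first 12 columns only
        aug = augment_dataset(train.responses, train.labels, target_count=augment_target, seed=seed)
        F12 = extract_feature_matrix(aug.samples, model.reference)[:, :12]
        m12 = train_classifier(F12, aug.labels, reference=model.reference, seed=seed)
        out["metrics_custom_only"] = evaluate(m12, Fe[:, :12], eval_.labels)
    return out
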