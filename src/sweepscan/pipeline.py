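"""End-to-end orchestration: corpus featurization, the scaled training
experiment, and the genome scan.

The scaled experiment reproduces the full-scale study design at desk
scale: 1.1 Mb feature windows (11 x 100 kb subwindows) instead of
2.75 Mb, with the selection-coefficient prior rescaled by the same
window-length ratio (s log-uniform on [0.002, 0.02]) so sweeps occupy the
same fraction of the window, a constant effective size of 5 x 10^4
(bottlenecked-population order; selection regime 2Ns in [200, 2000] and
soft sweeps from at most 2N*f0 = 5,000 founder copies), 20 diploid
samples, and 1,200 replicates per class split 900 train / 300 test.
See docs/methods.md for how these conditions were chosen and what they
do and do not reproduce of the full-scale regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CLASS_LABELS, DemographicModel, GenotypeMatrix, MaskProfile, RecombinationMap
from .classifier import ClassPosterior, SweepClassifier, binary_sweep_curves
from .featurize import DEFAULT_SUBWINDOWS, FeatureMatrix, featurize_window
from .scan import FilterReport, SweepCall, call_sweeps, enumerate_windows, filter_windows
from .synthetic_data import (
    LabeledReplicate,
    SimPriors,
    build_balanced_corpus,
    rescale_for_region,
)

# ---- scaled-down study conditions (fixed; see docs/methods.md) ------------
SCALED_WINDOW_LEN = 1_100_000
SCALED_NE = 5e4
SCALED_N_DIPLOIDS = 20
SCALED_N_PER_CLASS = 1200
SCALED_N_TRAIN_PER_CLASS = 900
SCALED_N_TEST_PER_CLASS = 300
#: cap on segregating sites per subwindow entering the LD statistics
SCALED_MAX_LD_SITES = 300


def scaled_priors(window_len: int = SCALED_WINDOW_LEN, n: int = SCALED_N_DIPLOIDS) -> SimPriors:
    """The full-scale priors rescaled to the desk-scale window length."""
    base = SimPriors(n=n)
    return rescale_for_region(base, window_len)


def corpus_features(
    corpus: Sequence[LabeledReplicate],
    k: int = DEFAULT_SUBWINDOWS,
    max_ld_sites: int | None = None,
) -> pd.DataFrame:
    """Feature table: one row per replicate, 12*k feature columns
    (named stat_subwindow), plus label and replicate metadata."""
    rows = []
    names = FeatureMatrix.feature_names(k)
    for i, rep in enumerate(corpus):
        fm = featurize_window(rep.genotypes, k=k, max_ld_sites=max_ld_sites)
        row = dict(zip(names, fm.flatten()))
        row["replicate_id"] = i
        row["label"] = rep.label
        if rep.params is not None:
            row.update(
                {
                    "mu": rep.params.mu,
                    "r": rep.params.r,
                    "s": rep.params.s,
                    "tau": rep.params.tau,
                    "f0": rep.params.f0,
                    "seed": rep.params.seed,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def features_matrix(df: pd.DataFrame, k: int = DEFAULT_SUBWINDOWS):
    names = FeatureMatrix.feature_names(k)
    return df[names].to_numpy(float), df["label"].to_numpy()


@dataclass
class ExperimentResult:
    """Trained classifier plus held-out evaluation of the scaled experiment."""

    model: SweepClassifier
    train_df: pd.DataFrame
    test_df: pd.DataFrame
    posteriors: np.ndarray  # test-set posteriors, CLASS_LABELS order
    truths: np.ndarray
    auc: float
    average_precision: float
    neutral_sweep_rate_argmax: float  # fraction, no threshold
    neutral_sweep_rate_at_080: float  # fraction, combined prob >= 0.80

    @property
    def neutral_probs(self) -> np.ndarray:
        """Null distribution: combined sweep probabilities of neutral tests."""
        neutral = self.truths == "neutral"
        return self.posteriors[neutral][:, 3] + self.posteriors[neutral][:, 4]


def neutral_misclassification_rates(
    posteriors: np.ndarray, truths: np.ndarray, threshold: float = 0.80
) -> tuple[float, float]:
    """(argmax rate, thresholded rate) of neutral examples called sweeps."""
    truths = np.asarray(truths)
    neutral = truths == "neutral"
    if not neutral.any():
        raise ValueError("no neutral examples")
    post = posteriors[neutral]
    argmax_sweep = np.isin(post.argmax(axis=1), (3, 4))
    combined = post[:, 3] + post[:, 4]
    return (
        float(argmax_sweep.mean()),
        float((argmax_sweep & (combined >= threshold)).mean()),
    )


def run_scaled_experiment(
    seed: int,
    n_per_class: int = SCALED_N_PER_CLASS,
    n_train_per_class: int = SCALED_N_TRAIN_PER_CLASS,
    n_test_per_class: int = SCALED_N_TEST_PER_CLASS,
    window_len: int = SCALED_WINDOW_LEN,
    ne: float = SCALED_NE,
    mask_library: Optional[Sequence[MaskProfile]] = None,
    max_ld_sites: Optional[int] = SCALED_MAX_LD_SITES,
) -> ExperimentResult:
    """Simulate the scaled corpus, train, and evaluate on held-out data."""
    if n_train_per_class + n_test_per_class > n_per_class:
        raise ValueError("train+test per class exceeds corpus size")
    priors = scaled_priors(window_len)
    demography = DemographicModel.constant(ne)
    corpus = build_balanced_corpus(
        priors, demography, n_per_class, mask_library=mask_library, seed=seed
    )
    rng = np.random.default_rng(seed + 1)
    from .synthetic_data import assemble_train_test

    train_set, test_set = assemble_train_test(
        corpus, n_train_per_class, n_test_per_class, rng
    )
    train_df = corpus_features(train_set, max_ld_sites=max_ld_sites)
    test_df = corpus_features(test_set, max_ld_sites=max_ld_sites)
    X_tr, y_tr = features_matrix(train_df)
    X_te, y_te = features_matrix(test_df)
    model = SweepClassifier(random_state=seed + 2).fit(X_tr, y_tr)
    probs = model.predict_proba(X_te)
    # expand to canonical order in case a class were absent (never at scale)
    posteriors = np.zeros((probs.shape[0], len(CLASS_LABELS)))
    for j, cls in enumerate(model.classes_):
        posteriors[:, CLASS_LABELS.index(cls)] = probs[:, j]
    _, _, auc, ap = binary_sweep_curves(posteriors, y_te)
    rate_argmax, rate_080 = neutral_misclassification_rates(posteriors, y_te)
    return ExperimentResult(
        model=model,
        train_df=train_df,
        test_df=test_df,
        posteriors=posteriors,
        truths=y_te,
        auc=auc,
        average_precision=ap,
        neutral_sweep_rate_argmax=rate_argmax,
        neutral_sweep_rate_at_080=rate_080,
    )


def classify_windows(
    model: SweepClassifier,
    gm_per_window: Sequence[GenotypeMatrix],
    k: int = DEFAULT_SUBWINDOWS,
    max_ld_sites: Optional[int] = None,
) -> list[ClassPosterior]:
    """Posterior per feature window."""
    out = []
    for gm in gm_per_window:
        fm = featurize_window(gm, k=k, max_ld_sites=max_ld_sites)
        probs = model.predict_proba(fm.flatten()[None, :])[0]
        full = np.zeros(len(CLASS_LABELS))
        for j, cls in enumerate(model.classes_):
            full[CLASS_LABELS.index(cls)] = probs[j]
        out.append(ClassPosterior.from_array(full))
    return out


def scan_genome(
    model: SweepClassifier,
    read_window,
    chrom_lengths: dict[str, int],
    window_len: int,
    rmap: Optional[RecombinationMap] = None,
    masks: Optional[Sequence[MaskProfile]] = None,
    threshold: Optional[float] = 0.8,
    k: int = DEFAULT_SUBWINDOWS,
    step: Optional[int] = None,
    max_masked_fraction: float = 0.85,
    max_ld_sites: Optional[int] = None,
) -> tuple[list[SweepCall], FilterReport]:
    """Sliding-window scan over a genome.

    ``read_window`` is a callable mapping a feature-window GenomicInterval
    to a GenotypeMatrix (e.g. a VCF reader closure), keeping the scan
    independent of the storage backend.
    """
    step = step or window_len // k
    windows = enumerate_windows(chrom_lengths, window_len, step, k=k)
    retained, report = filter_windows(
        windows, rmap, masks, max_masked_fraction=max_masked_fraction
    )
    gms = [read_window(fw) for fw, _ in retained]
    posteriors = classify_windows(model, gms, k=k, max_ld_sites=max_ld_sites)
    decisions = call_sweeps(posteriors, threshold)
    calls = [
        SweepCall(window=cw, feature_window=fw, posterior=post, decision=dec)
        for (fw, cw), post, dec in zip(retained, posteriors, decisions)
    ]
    return calls, report


def attach_qvalues(
    calls: Sequence[SweepCall],
    null_probs: np.ndarray,
    n_windows: Optional[int] = None,
) -> list[SweepCall]:
    """Compute q-values for called sweeps and attach them in place."""
    from .inference_stats import NullDistribution, qvalues

    null = NullDistribution(null_probs)
    all_probs = np.array([c.combined_sweep_prob for c in calls])
    sweep_idx = [i for i, c in enumerate(calls) if c.is_sweep]
    if sweep_idx:
        cand = all_probs[sweep_idx]
        qs = qvalues(cand, all_probs, null, n_windows or len(calls))
        for i, q in zip(sweep_idx, qs):
            calls[i].q_value = float(q)
    return list(calls)
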