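"""Quantitative evaluation: Fréchet distance between feature distributions
and summary statistics of the histopathologist survey.

The Fréchet distance between Gaussian fits N(mu1, S1), N(mu2, S2) of deep
feature distributions is

    d^2 = ||mu1 - mu2||^2 + Tr(S1 + S2 - 2 (S1 S2)^{1/2})

(lower is better). Feature extraction is pluggable: an inception-style
pretrained network needs a downloaded checkpoint and is intentionally not
bundled; the default is a small fixed-seed random convolutional extractor
which makes the metric cheap, deterministic and suitable for tracking
relative progress on synthetic data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, no_grad
from . import nn


@dataclass
class FeatureSet:
    features: np.ndarray     # [N, D]
    extractor_id: str

    def validate(self):
        if self.features.ndim != 2 or self.features.shape[0] < 2:
            raise ValueError("need an [N>=2, D] feature array")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite features")
        return self


class ToyFeatureExtractor:
    """Fixed-seed random two-layer conv net + moment pooling.

    Random convolutional features preserve enough distributional information
    to compare image sets at desk scale; identical seeds give identical
    extractors, so distances are reproducible.
    """

    def __init__(self, seed: int = 0, channels: tuple[int, int] = (8, 16)):
        rng = np.random.default_rng(seed)
        self.conv1 = nn.Conv2d(3, channels[0], 3, rng, stride=2)
        self.conv2 = nn.Conv2d(channels[0], channels[1], 3, rng, stride=2)
        self.extractor_id = f"toy-conv-seed{seed}-c{channels[0]}x{channels[1]}"

    def __call__(self, images: np.ndarray) -> FeatureSet:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim != 4:
            raise ValueError("expected [N,3,H,W] images")
        with no_grad():
            h = ad.leaky_relu(self.conv1(Tensor(x)), 0.1)
            h = ad.leaky_relu(self.conv2(h), 0.1).data
        mean = h.mean(axis=(2, 3))
        std = h.std(axis=(2, 3))
        return FeatureSet(np.concatenate([mean, std], axis=1),
                          self.extractor_id).validate()


def _sqrtm_psd(mat: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition; tiny negative
    eigenvalues from round-off are clamped to zero."""
    sym = (mat + mat.T) / 2.0
    lam, vec = np.linalg.eigh(sym)
    lam = np.clip(lam, 0.0, None)
    return (vec * np.sqrt(lam)) @ vec.T


def frechet_distance(mean1, cov1, mean2, cov2) -> float:
    """Fréchet distance between two Gaussians (squared-distance convention)."""
    mu1, mu2 = np.atleast_1d(np.asarray(mean1, float)), np.atleast_1d(np.asarray(mean2, float))
    s1, s2 = np.atleast_2d(np.asarray(cov1, float)), np.atleast_2d(np.asarray(cov2, float))
    if mu1.shape != mu2.shape or s1.shape != s2.shape or s1.shape[0] != mu1.size:
        raise ValueError("dimension mismatch between means/covariances")
    diff = mu1 - mu2
    rs1 = _sqrtm_psd(s1)
    cross = _sqrtm_psd(rs1 @ s2 @ rs1)   # Tr((S1 S2)^{1/2}) = Tr((S1^{1/2} S2 S1^{1/2})^{1/2})
    val = float(diff @ diff + np.trace(s1) + np.trace(s2) - 2.0 * np.trace(cross))
    return max(val, 0.0)


def fid(real: FeatureSet, fake: FeatureSet) -> float:
    """Fréchet distance between Gaussian fits of two feature sets."""
    real.validate()
    fake.validate()
    if real.extractor_id != fake.extractor_id:
        raise ValueError("feature sets come from different extractors")
    mu_r, mu_f = real.features.mean(axis=0), fake.features.mean(axis=0)
    s_r = np.cov(real.features, rowvar=False)
    s_f = np.cov(fake.features, rowvar=False)
    return frechet_distance(mu_r, s_r, mu_f, s_f)


def fid_domain_average(real_a: FeatureSet, fake_a: FeatureSet,
                       real_b: FeatureSet, fake_b: FeatureSet) -> float:
    """Mean of the two per-domain distances (one score for the whole model)."""
    return 0.5 * (fid(real_a, fake_a) + fid(real_b, fake_b))


# ---------------------------------------------------------------------------
# survey statistics
# ---------------------------------------------------------------------------

@dataclass
class SurveyRow:
    pair: str
    correct: int
    incorrect: int
    avg_rating: float


@dataclass
class SurveyTable:
    """Per-pair guess counts and mean realism ratings (1-6 scale).

    Raters judged which of two images (generated vs ground truth) is real and
    rated the generated image's realism; incorrect guesses score realism 6.
    """

    rows: list[SurveyRow]
    rater_count: int

    def validate(self):
        if not self.rows:
            raise ValueError("empty survey table")
        for r in self.rows:
            if r.correct + r.incorrect != self.rater_count:
                raise ValueError(
                    f"pair {r.pair}: correct+incorrect != rater count {self.rater_count}")
            if not 1.0 <= r.avg_rating <= 6.0:
                raise ValueError(f"pair {r.pair}: rating {r.avg_rating} outside [1,6]")
        return self


@dataclass
class SurveySummary:
    total_correct: int
    total_incorrect: int
    percent_correct: float
    overall_realism: float


def survey_summary(table: SurveyTable) -> SurveySummary:
    """Column totals, identification rate, and the overall realism average.

    Published per-pair averages are rounded; the integer rating sum of each
    pair is recovered as round(avg * raters) before averaging overall, so the
    summary matches what exact per-rater scores would give.
    """
    table.validate()
    correct = sum(r.correct for r in table.rows)
    incorrect = sum(r.incorrect for r in table.rows)
    percent = round(100.0 * correct / (correct + incorrect), 2)
    rating_sum = sum(round(r.avg_rating * table.rater_count) for r in table.rows)
    realism = round(rating_sum / (len(table.rows) * table.rater_count), 2)
    return SurveySummary(total_correct=correct, total_incorrect=incorrect,
                         percent_correct=percent, overall_realism=realism)


def read_survey_tsv(path) -> SurveyTable:
    """Read a TSV with columns: pair, correct, incorrect, avg_rating."""
    rows = []
    with open(path) as fh:
        rd = csv.DictReader(fh, delimiter="\t")
        for rec in rd:
            rows.append(SurveyRow(pair=rec["pair"], correct=int(rec["correct"]),
                                  incorrect=int(rec["incorrect"]),
                                  avg_rating=float(rec["avg_rating"])))
    counts = {r.correct + r.incorrect for r in rows}
    if len(counts) != 1:
        raise ValueError("inconsistent rater counts across pairs")
    return SurveyTable(rows=rows, rater_count=counts.pop()).validate()
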