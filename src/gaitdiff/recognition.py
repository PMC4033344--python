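"""Gallery/probe identification and verification.

Identification is nearest-neighbour over feature-matrix distances: a probe
is assigned the label of the closest gallery entry, and the full ranking
yields the cumulative match characteristic (CMC).  Verification scores a
probe against every gallery entry with the similarity ``Sim = -distance``,
z-normed per probe over the gallery (subtract the mean, divide by the
sample standard deviation); sweeping a threshold over genuine and impostor
scores gives FAR/FRR curves and the equal error rate (EER).

``NearestTemplateClassifier`` packages the gallery as a scikit-learn
classifier; ``evaluate`` runs the whole template -> basis -> feature ->
metric pipeline on labeled silhouette sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .features import TwoDPCA, VectorizedPCA, feature_distance
from .templates import SilhouetteSequence, build_template

__all__ = [
    "NearestTemplateClassifier",
    "EvaluationReport",
    "identify",
    "similarity",
    "znorm_similarities",
    "roc_and_eer",
    "evaluate",
]


def _stack_features(features) -> np.ndarray:
    F = np.asarray(features, float)
    if F.ndim == 2:  # vectorized-PCA d-vectors
        return F
    if F.ndim == 3:
        return F
    raise ValueError("features must be (M, d) vectors or (M, m, d) matrices")


def _distance_row(P: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Distances from one probe feature to every row of a feature stack."""
    if F.ndim == 2:
        return np.linalg.norm(F - P, axis=1)
    return np.linalg.norm(F - P, axis=1).sum(axis=1)


class NearestTemplateClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-neighbour matcher over gait feature matrices.

    ``fit`` enrolls gallery features (``(M, m, d)`` matrices or ``(M, d)``
    vectors) with subject labels; ``predict`` assigns each probe the label
    of the closest gallery entry.  Ties are broken by gallery insertion
    order (first enrolled wins).
    """

    def fit(self, X, y) -> "NearestTemplateClassifier":
        F = _stack_features(X)
        y = np.asarray(y)
        if len(y) != F.shape[0]:
            raise ValueError("label count does not match feature count")
        if F.shape[0] == 0:
            raise ValueError("cannot fit an empty gallery")
        self.gallery_features_ = F
        self.gallery_labels_ = y
        self.classes_ = np.unique(y)
        return self

    def _check_probe(self, P: np.ndarray) -> np.ndarray:
        P = np.asarray(P, float)
        if P.shape != self.gallery_features_.shape[1:]:
            raise ValueError(
                f"probe feature shape {P.shape} does not match gallery "
                f"{self.gallery_features_.shape[1:]}"
            )
        return P

    def decision_distances(self, X) -> np.ndarray:
        """(n_probes, M) matrix of probe-to-gallery feature distances."""
        check_is_fitted(self, "gallery_features_")
        F = _stack_features(X)
        if F.shape[1:] != self.gallery_features_.shape[1:]:
            raise ValueError("probe feature shape does not match gallery")
        return np.stack([_distance_row(P, self.gallery_features_) for P in F])

    def rank(self, P) -> list[tuple[object, float]]:
        """Full gallery ranking for one probe: (label, distance), ascending.

        The sort is stable, so equal distances keep insertion order.
        """
        check_is_fitted(self, "gallery_features_")
        d = _distance_row(self._check_probe(P), self.gallery_features_)
        order = np.argsort(d, kind="stable")
        return [(self.gallery_labels_[i], float(d[i])) for i in order]

    def predict(self, X) -> np.ndarray:
        D = self.decision_distances(X)
        return self.gallery_labels_[D.argmin(axis=1)]

    def znorm_scores(self, P) -> list[tuple[object, float]]:
        """Z-normed similarities of one probe to every gallery entry.

        Similarities (negative distances) are standardized by their own
        mean and sample standard deviation (divisor M - 1) over the
        gallery.  All-equal similarities raise (degenerate probe).
        """
        check_is_fitted(self, "gallery_features_")
        if self.gallery_features_.shape[0] < 2:
            raise ValueError("z-norming needs a gallery of at least 2 entries")
        sims = -_distance_row(self._check_probe(P), self.gallery_features_)
        sd = sims.std(ddof=1)
        if sd == 0:
            raise ValueError("degenerate probe: all gallery similarities are equal")
        z = (sims - sims.mean()) / sd
        return list(zip(self.gallery_labels_.tolist(), z.tolist()))


# ---------------------------------------------------------------------------
# function-style wrappers


def identify(P, gallery: NearestTemplateClassifier):
    """Nearest-neighbour identification of one probe feature matrix.

    Returns ``(subject_id, ranking)`` where ranking is the full list of
    (subject_id, distance) pairs sorted by ascending distance.
    """
    ranking = gallery.rank(P)
    return ranking[0][0], ranking


def similarity(Ya, Yb) -> float:
    """Similarity of two feature matrices: the negative of their distance."""
    return -feature_distance(Ya, Yb)


def znorm_similarities(P, gallery: NearestTemplateClassifier):
    return gallery.znorm_scores(P)


def roc_and_eer(genuine_scores, impostor_scores):
    """FAR/FRR curve and equal error rate from verification scores.

    Sweeping a threshold t over the union of observed scores,
    ``FAR(t)`` is the fraction of impostor scores >= t and ``FRR(t)`` the
    fraction of genuine scores < t.  The EER is taken where FAR = FRR,
    linearly interpolating between the two bracketing thresholds.

    Returns ``(roc, eer)`` with roc a list of (threshold, FAR, FRR).
    """
    genuine = np.asarray(list(genuine_scores), float)
    impostor = np.asarray(list(impostor_scores), float)
    if genuine.size == 0 or impostor.size == 0:
        raise ValueError("genuine and impostor score lists must be nonempty")
    thresholds = np.unique(np.concatenate([genuine, impostor]))
    # pad so the sweep starts at FAR=1/FRR=0 and ends at FAR=0/FRR=1
    lo = thresholds[0] - 1.0
    hi = thresholds[-1] + 1.0
    thresholds = np.concatenate([[lo], thresholds, [hi]])
    far = np.array([(impostor >= t).mean() for t in thresholds])
    frr = np.array([(genuine < t).mean() for t in thresholds])
    diff = far - frr  # non-increasing in t, from +1 to -1
    k = int(np.argmax(diff <= 0))
    if diff[k] == 0:
        eer = float(far[k])
    else:
        # interpolate between thresholds k-1 (diff > 0) and k (diff < 0)
        f0, f1 = far[k - 1], far[k]
        r0, r1 = frr[k - 1], frr[k]
        denom = (f1 - f0) - (r1 - r0)
        alpha = (r0 - f0) / denom if denom != 0 else 0.5
        eer = float(f0 + alpha * (f1 - f0))
    roc = list(zip(thresholds.tolist(), far.tolist(), frr.tolist()))
    return roc, eer


@dataclass
class EvaluationReport:
    """Identification and verification results for one gallery/probe run."""

    cmc: np.ndarray  # cmc[r-1] = fraction of probes with true id in top r
    roc: list[tuple[float, float, float]]  # (threshold, FAR, FRR)
    eer: float
    rank1: float
    distance_matrix: np.ndarray  # (n_probes, n_gallery)
    probe_labels: np.ndarray
    gallery_labels: np.ndarray
    protocol: str = "plain"
    n_forced_errors: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def rank5(self) -> float:
        r = min(5, len(self.cmc))
        return float(self.cmc[r - 1])


def _features_for(extractor, templates) -> np.ndarray:
    return extractor.transform(np.stack([t.values for t in templates]))


def evaluate(
    gallery_sequences: list[SilhouetteSequence],
    probe_sequences: list[SilhouetteSequence],
    *,
    kind: str = "agdi",
    method: str = "2dpca",
    n_components: int = 20,
    protocol: str = "plain",
) -> EvaluationReport:
    """Run the full pipeline on labeled sequences and score it.

    Templates of the requested ``kind`` are built per sequence; the
    projection basis is fitted on the gallery templates only; probes are
    identified by nearest neighbour (CMC) and verified via z-normed
    similarities, with same-subject probe/gallery pairs as genuine trials
    and all others as impostors.

    ``protocol='leave-one-out'`` refits the basis for each probe with the
    same-subject gallery sequence excluded from basis training (the gallery
    itself still contains every subject when scoring).
    """
    if protocol not in ("plain", "leave-one-out"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if method not in ("2dpca", "pca"):
        raise ValueError(f"unknown feature method {method!r}")

    g_templates = [build_template(s, kind) for s in gallery_sequences]
    p_templates = [build_template(s, kind) for s in probe_sequences]
    g_labels = np.array([s.subject_id for s in gallery_sequences])
    p_labels = np.array([s.subject_id for s in probe_sequences])

    def make_extractor():
        if method == "2dpca":
            return TwoDPCA(n_components=n_components)
        return VectorizedPCA(n_components=n_components)

    g_stack = np.stack([t.values for t in g_templates])

    def fit_and_score(probe_template, exclude_subject):
        if protocol == "leave-one-out":
            keep = g_labels != exclude_subject
            if keep.sum() < 2:
                keep = np.ones(len(g_labels), bool)
            extractor = make_extractor().fit(g_stack[keep])
        else:
            extractor = shared_extractor
        gallery = NearestTemplateClassifier().fit(
            _features_for(extractor, g_templates), g_labels
        )
        P = extractor.transform(probe_template.values[None])[0]
        return gallery, P

    shared_extractor = make_extractor().fit(g_stack) if protocol == "plain" else None

    n_gallery = len(g_templates)
    cmc_hits = np.zeros(n_gallery)
    dist_rows = []
    genuine, impostor = [], []
    forced = 0
    for pt, pl in zip(p_templates, p_labels):
        gallery, P = fit_and_score(pt, pl)
        d = _distance_row(P, gallery.gallery_features_)
        dist_rows.append(d)
        order = np.argsort(d, kind="stable")
        ranked_labels = g_labels[order]
        if pl not in g_labels:
            forced += 1  # probe identity not enrolled: an unconditional miss
        else:
            first_hit = int(np.nonzero(ranked_labels == pl)[0][0])
            cmc_hits[first_hit:] += 1
        try:
            for lab, z in gallery.znorm_scores(P):
                (genuine if lab == pl else impostor).append(z)
        except ValueError:
            forced += 0  # degenerate probe: contributes no verification trials

    n_probes = len(p_templates)
    cmc = cmc_hits / n_probes if n_probes else cmc_hits
    if genuine and impostor:
        roc, eer = roc_and_eer(genuine, impostor)
    else:
        roc, eer = [], float("nan")
    return EvaluationReport(
        cmc=cmc,
        roc=roc,
        eer=eer,
        rank1=float(cmc[0]) if n_probes else float("nan"),
        distance_matrix=np.stack(dist_rows) if dist_rows else np.zeros((0, n_gallery)),
        probe_labels=p_labels,
        gallery_labels=g_labels,
        protocol=protocol,
        n_forced_errors=forced,
        metadata={"kind": kind, "method": method, "n_components": n_components},
    )
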