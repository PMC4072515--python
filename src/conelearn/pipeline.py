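"""End-to-end orchestration and evaluation metrics.

`run_pipeline` wires the whole method together: synthesize scenes, build a
mosaic, stream patch responses (with optional surround, noise, blur, and
stride), accumulate the cone correlation matrix, and hand it to
:class:`ConeClassifier` — the scikit-learn-style estimator implementing the
unsupervised algorithm (correlation -> -log -> non-metric MDS -> S-cone
identification -> rotation -> quadratic flattening -> skew-normal mixture
selection -> per-cone labels).

Evaluation follows the class-averaged convention: the reported accuracy is
the mean over longer-wavelength classes of each class's correct fraction,
which keeps a majority class from masking failures on a rare one (354/354 L
plus 1/22 M is 52% balanced, not 94% overall).  Detection compares the
selected number of longer-wavelength classes against the truth, and spatial
recovery measures how well the embedding's spatial plane reproduces the
mosaic geometry under a rigid (rotation/reflection/translation) alignment.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.linalg import orthogonal_procrustes
from sklearn.base import BaseEstimator

from . import classify as _classify
from .correlation import CorrelationAccumulator, CorrelationMatrix, to_dissimilarity
from .embedding import Embedding, identify_s_cones, nmds, rotate_embedding
from .flatten import FlattenedPositions, fit_surface, flatten
from .mosaic import ConeClassSpec, Mosaic, build_mosaic
from .responses import SurroundSpec, gather_responses, project_scene, surround_matrix
from .scenes import SceneModel, blur_image, generate_scene, sample_offsets
from .spectra import cone_fundamental

__all__ = [
    "RunConfig",
    "EvaluationReport",
    "PipelineResult",
    "ConeClassifier",
    "balanced_accuracy",
    "detection_outcome",
    "spatial_recovery",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Complete parameter set of one simulation + learning run.

    Longer-wavelength classes are given as (name, lambda_max, ratio) tuples;
    the S class is implicit (fraction ``s_fraction``, peak ``lambda_s``).
    The config is fully serialized into every report for provenance.
    """

    # mosaic
    side: int = 20
    lw_classes: tuple[tuple[str, float, float], ...] = (
        ("L", 558.9, 1.0),
        ("M", 530.0, 1.0),
    )
    s_fraction: float = 0.06
    lambda_s: float = 420.7
    min_s_spacing: float = 2.5
    # scenes
    n_scenes: int = 8
    scene_size: int = 256
    spatial_exponent: float = 2.2
    spectral_corr_scale: float = 100.0
    luminance_weight: float = 0.3
    mean_level: float = 1.0
    contrast: float = 0.35
    blur_sigma: float = 0.0
    # responses
    n_patches: int = 100_000
    stride: int = 1
    batch_size: int = 5_000
    surround_mode: str = "uniform"
    surround_sigma: float = 2.0
    surround_weight: float = 0.25
    support_radius: float = 5.0
    noise_fraction: float = 0.0
    noise_reference: str = "patch"
    # analysis
    corr_floor: float = 1e-6
    nmds_max_iter: int = 300
    nmds_tol: float = 1e-6
    alpha: float = 0.01
    k_max: int = 3
    mixture_restarts: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side < 2:
            raise ValueError("mosaic side must be at least 2")
        if not self.lw_classes:
            raise ValueError("need at least one longer-wavelength class")
        if self.n_patches < 2:
            raise ValueError("need at least 2 patches")
        scene_extent = (self.side - 1) * self.stride + 1
        if self.scene_size < scene_extent:
            raise ValueError("scene_size too small for the mosaic at this stride")
        SurroundSpec(  # validates surround parameters
            mode=self.surround_mode,
            sigma=self.surround_sigma,
            total_weight=self.surround_weight,
            support_radius=self.support_radius,
        )

    @property
    def patch_size(self) -> int:
        return (self.side - 1) * self.stride + 1

    @property
    def true_k(self) -> int:
        return len(self.lw_classes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lw_classes"] = [list(t) for t in self.lw_classes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "lw_classes" in d:
            d["lw_classes"] = tuple(tuple(t) for t in d["lw_classes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class EvaluationReport:
    """Per-run evaluation: detection, accuracies, and spatial recovery."""

    selected_k: int
    true_k: int
    detection: str
    balanced_accuracy: float
    overall_accuracy: float
    per_class_accuracy: dict[str, float]
    s_identification_accuracy: float
    spatial_residual: float
    stress: float
    adequate_fit: bool
    confusion: dict[str, dict[str, int]]
    config: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    report: EvaluationReport
    mosaic: Mosaic
    correlation: CorrelationMatrix
    embedding: Embedding
    flattened: FlattenedPositions
    classification: _classify.ClassificationResult
    classifier: "ConeClassifier"


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def balanced_accuracy(
    labels_true: np.ndarray,
    labels_pred: np.ndarray,
    classes: Sequence,
) -> tuple[float, float]:
    """Class-averaged and overall correct fractions.

    The balanced value is the mean over ``classes`` of each class's correct
    fraction; the overall value is the plain fraction correct over all
    entries whose true label is in ``classes``.  An empty class raises.
    """
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if labels_true.shape != labels_pred.shape:
        raise ValueError("label vectors must have equal length")
    if len(classes) == 0:
        raise ValueError("classes must be nonempty")
    per_class = []
    n_total = n_correct = 0
    for cls in classes:
        mask = labels_true == cls
        if not np.any(mask):
            raise ValueError(f"class {cls!r} has no members")
        hits = int(np.sum(labels_pred[mask] == cls))
        per_class.append(hits / int(mask.sum()))
        n_correct += hits
        n_total += int(mask.sum())
    return float(np.mean(per_class)), n_correct / n_total


def detection_outcome(selected_k: int, true_k: int) -> str:
    """'correct', 'under_detected', or 'over_detected'."""
    if selected_k < 1 or true_k < 1:
        raise ValueError("class counts must be at least 1")
    if selected_k == true_k:
        return "correct"
    return "under_detected" if selected_k < true_k else "over_detected"


def spatial_recovery(
    embedding_xy: np.ndarray, mosaic_xy: np.ndarray
) -> tuple[np.ndarray, float]:
    """Rigidly align embedded spatial positions to the true mosaic grid.

    Orthogonal Procrustes (rotation + reflection + translation, no scaling)
    minimizing the summed squared error; returns the aligned coordinates and
    the RMS residual in embedding units.
    """
    A = np.asarray(embedding_xy, dtype=float)
    B = np.asarray(mosaic_xy, dtype=float)
    if A.shape != B.shape or A.shape[0] < 3:
        raise ValueError("need matching coordinate sets with at least 3 points")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    if np.allclose(Ac, 0) or np.allclose(Bc, 0):
        raise ValueError("degenerate (all-coincident) coordinates cannot be aligned")
    R, _ = orthogonal_procrustes(Ac, Bc)
    aligned = Ac @ R + B.mean(axis=0)
    residual = float(np.sqrt(np.mean(np.sum((aligned - B) ** 2, axis=1))))
    return aligned, residual


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------


class ConeClassifier(BaseEstimator):
    """Unsupervised spectral-class learner for a cone mosaic.

    ``fit`` consumes either a precomputed cone correlation matrix
    (``input_type='correlation'``) or a response matrix of shape
    (n_patches, n_cones) (``input_type='responses'``) and recovers the
    number of longer-wavelength classes and a per-cone label.

    Attributes (after fit)
    ----------------------
    correlation_, dissimilarity_ : the pairwise statistics.
    embedding_ : rotated 3-D coordinates (dim 1 = spectral axis).
    stress_ : final STRESS1 of the embedding.
    s_cone_mask_ : boolean mask of cones identified as S.
    flattened_ : signed flattened position per cone (NaN for S cones).
    selected_k_ : number of longer-wavelength classes chosen by the KS sweep.
    labels_ : int per cone; -1 for S, otherwise the class rank by distance
        from the S cones (0 = nearest, i.e. lowest inferred peak wavelength).
    threshold_ : two-class decision boundary when ``selected_k_ == 2``.
    """

    def __init__(
        self,
        input_type: str = "correlation",
        corr_floor: float = 1e-6,
        n_components: int = 3,
        nmds_max_iter: int = 300,
        nmds_tol: float = 1e-6,
        k_max: int = 3,
        alpha: float = 0.01,
        mixture_restarts: int = 20,
        kmeans_restarts: int = 10,
        manual_rotation: np.ndarray | None = None,
        manual_s_side: float = -1.0,
        random_state: int | None = 0,
    ):
        self.input_type = input_type
        self.corr_floor = corr_floor
        self.n_components = n_components
        self.nmds_max_iter = nmds_max_iter
        self.nmds_tol = nmds_tol
        self.k_max = k_max
        self.alpha = alpha
        self.mixture_restarts = mixture_restarts
        self.kmeans_restarts = kmeans_restarts
        self.manual_rotation = manual_rotation
        self.manual_s_side = manual_s_side
        self.random_state = random_state

    def _to_correlation(self, X) -> CorrelationMatrix:
        if isinstance(X, CorrelationMatrix):
            return X
        X = np.asarray(X, dtype=float)
        if self.input_type == "correlation":
            return CorrelationMatrix(rho=X, n_patches=0)
        if self.input_type != "responses":
            raise ValueError(f"unknown input_type {self.input_type!r}")
        acc = CorrelationAccumulator(X.shape[1])
        acc.update(X.T)
        return acc.finalize()

    def fit(self, X, y=None) -> "ConeClassifier":
        corr = self._to_correlation(X)
        self.correlation_ = corr
        self.dissimilarity_ = to_dissimilarity(corr, floor=self.corr_floor)
        emb = nmds(
            self.dissimilarity_,
            dim=self.n_components,
            max_iter=self.nmds_max_iter,
            tol=self.nmds_tol,
        )
        n = emb.coords.shape[0]
        if self.manual_rotation is not None:
            # tritanope hook: no S cones to anchor the rotation
            R = np.asarray(self.manual_rotation, dtype=float)
            emb = Embedding(
                emb.coords @ R.T, emb.stress, emb.iterations, emb.converged,
                emb.stress_history,
            )
            s_mask = np.zeros(n, dtype=bool)
            side_sign: float | None = float(self.manual_s_side)
        else:
            s_mask = identify_s_cones(
                emb, seed=self.random_state, n_restarts=self.kmeans_restarts
            )
            emb = rotate_embedding(emb, s_mask)
            side_sign = None
        self.embedding_ = emb
        self.stress_ = emb.stress
        self.s_cone_mask_ = s_mask

        non_s = ~s_mask
        self.surface_ = fit_surface(emb.coords, non_s)
        flat = flatten(
            emb.coords,
            self.surface_,
            s_mask if s_mask.any() else None,
            s_side_sign=side_sign,
        )
        self.flattened_pos_ = flat
        self.flattened_ = np.full(n, np.nan)
        self.flattened_[flat.cone_indices] = flat.values

        sel = _classify.select_k(
            flat.values,
            k_max=self.k_max,
            alpha=self.alpha,
            restarts=self.mixture_restarts,
            seed=self.random_state,
        )
        self.selection_ = sel
        self.selected_k_ = sel.k
        self.adequate_fit_ = sel.adequate
        self.mixture_fits_ = sel.fits
        self.classification_ = _classify.assign_classes(
            flat.values, sel.best, s_side_sign=flat.s_side_sign, all_fits=sel.fits
        )
        self.labels_ = self._expand_labels(self.classification_.labels)
        self.threshold_ = self.classification_.threshold
        return self

    def _expand_labels(self, lw_labels: np.ndarray) -> np.ndarray:
        labels = np.full(self.s_cone_mask_.size, -1, dtype=int)
        labels[self.flattened_pos_.cone_indices] = lw_labels
        return labels

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def labels_for_k(self, k: int) -> np.ndarray:
        """Per-cone labels with the class count forced to ``k``.

        Reuses the fitted embedding and flattening; fits (or reuses) the
        K = ``k`` mixture and assigns classes from it.  Used to score
        classification separately from detection.
        """
        if k <= len(self.mixture_fits_):
            fit = self.mixture_fits_[k - 1]
        else:
            fit = _classify.fit_mixture(
                self.flattened_pos_.values,
                k,
                restarts=self.mixture_restarts,
                seed=self.random_state,
            )
        result = _classify.assign_classes(
            self.flattened_pos_.values, fit, s_side_sign=self.flattened_pos_.s_side_sign
        )
        return self._expand_labels(result.labels)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _simulate_correlation(
    config: RunConfig, mosaic: Mosaic, seeds: dict[str, np.random.Generator]
) -> CorrelationMatrix:
    """Stream patch responses through surround/noise into the correlation."""
    class_order = sorted(mosaic.lambda_max)
    fundamentals = {
        name: cone_fundamental(mosaic.lambda_max[name]) for name in class_order
    }
    scene_rng = seeds["scenes"]
    scenes = []
    for _ in range(config.n_scenes):
        model = SceneModel(
            size=config.scene_size,
            spatial_exponent=config.spatial_exponent,
            spectral_corr_scale=config.spectral_corr_scale,
            luminance_weight=config.luminance_weight,
            mean_level=config.mean_level,
            contrast=config.contrast,
            seed=int(scene_rng.integers(2**31 - 1)),
        )
        scene = generate_scene(model)
        if config.blur_sigma > 0:
            scene = blur_image(scene, config.blur_sigma)
        scenes.append(scene)
    projections = [project_scene(s, fundamentals, class_order) for s in scenes]

    spec = SurroundSpec(
        mode=config.surround_mode,
        sigma=config.surround_sigma,
        total_weight=config.surround_weight,
        support_radius=config.support_radius,
    )
    W = surround_matrix(mosaic, spec) if spec.mode != "none" else None

    shapes = [(s.cube.shape[0], s.cube.shape[1]) for s in scenes]
    img_idx, rows, cols = sample_offsets(
        shapes, config.patch_size, config.n_patches, seeds["patches"]
    )
    noise_rng = seeds["noise"]
    acc = CorrelationAccumulator(mosaic.n_cones)
    for start in range(0, config.n_patches, config.batch_size):
        sl = slice(start, min(start + config.batch_size, config.n_patches))
        values = gather_responses(
            projections, mosaic, class_order, img_idx[sl], rows[sl], cols[sl],
            stride=config.stride,
        )
        if W is not None:
            values = values - W @ values
        if config.noise_fraction > 0:
            if config.noise_reference == "patch":
                scale = config.noise_fraction * values.mean(axis=0, keepdims=True)
            else:
                scale = config.noise_fraction * values.mean()
            values = values + noise_rng.standard_normal(values.shape) * scale
        acc.update(values)
    return acc.finalize()


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full simulation + learning + evaluation run.

    Deterministic given the config (all randomness derives from
    ``config.seed``); identical configs produce identical reports.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(5)
    seeds = {
        "scenes": np.random.default_rng(children[0]),
        "mosaic": int(children[1].generate_state(1)[0] % (2**31 - 1)),
        "patches": np.random.default_rng(children[2]),
        "noise": np.random.default_rng(children[3]),
        "analysis": int(children[4].generate_state(1)[0] % (2**31 - 1)),
    }
    specs = [ConeClassSpec(name, lm) for name, lm, _ in config.lw_classes]
    ratios = [ratio for _, _, ratio in config.lw_classes]
    mosaic = build_mosaic(
        config.side,
        specs,
        ratios,
        s_fraction=config.s_fraction,
        min_s_spacing=config.min_s_spacing,
        seed=seeds["mosaic"],
        s_spec=ConeClassSpec("S", config.lambda_s),
    )
    corr = _simulate_correlation(config, mosaic, seeds)

    clf = ConeClassifier(
        input_type="correlation",
        corr_floor=config.corr_floor,
        nmds_max_iter=config.nmds_max_iter,
        nmds_tol=config.nmds_tol,
        k_max=config.k_max,
        alpha=config.alpha,
        mixture_restarts=config.mixture_restarts,
        random_state=seeds["analysis"],
    ).fit(corr)

    report = _evaluate(config, mosaic, clf)
    result = PipelineResult(
        report=report,
        mosaic=mosaic,
        correlation=corr,
        embedding=clf.embedding_,
        flattened=clf.flattened_pos_,
        classification=clf.classification_,
        classifier=clf,
    )
    if outdir is not None:
        _persist(result, Path(outdir))
    return result


def _evaluate(config: RunConfig, mosaic: Mosaic, clf: ConeClassifier) -> EvaluationReport:
    true_k = config.true_k
    # true labels as ranks by ascending lambda-max (S cones are -1), matching
    # the S-anchored ordering of the predicted classes
    lw_sorted = mosaic.lw_class_names
    rank_of_name = {name: r for r, name in enumerate(lw_sorted)}
    truth = np.array(
        [rank_of_name.get(name, -1) for name in mosaic.label_vector], dtype=int
    )
    pred = clf.labels_for_k(true_k)

    lw_mask = truth >= 0
    classes = list(range(true_k))
    bal, overall = balanced_accuracy(truth[lw_mask], pred[lw_mask], classes)
    per_class = {}
    for name in lw_sorted:
        r = rank_of_name[name]
        mask = truth == r
        per_class[name] = float(np.mean(pred[mask] == r))
    s_acc = float(np.mean((truth == -1) == clf.s_cone_mask_))

    confusion: dict[str, dict[str, int]] = {}
    names_by_rank = {-1: "S", **{r: n for n, r in rank_of_name.items()}}
    for t in sorted(set(truth)):
        row: dict[str, int] = {}
        for p in sorted(set(pred)):
            cnt = int(np.sum((truth == t) & (pred == p)))
            if cnt:
                row[names_by_rank.get(p, str(p))] = cnt
        confusion[names_by_rank.get(t, str(t))] = row

    _, residual = spatial_recovery(
        clf.embedding_.coords[lw_mask][:, 1:3], mosaic.coords[lw_mask]
    )
    return EvaluationReport(
        selected_k=clf.selected_k_,
        true_k=true_k,
        detection=detection_outcome(clf.selected_k_, true_k),
        balanced_accuracy=bal,
        overall_accuracy=overall,
        per_class_accuracy=per_class,
        s_identification_accuracy=s_acc,
        spatial_residual=residual,
        stress=clf.stress_,
        adequate_fit=clf.adequate_fit_,
        confusion=confusion,
        config=config.to_dict(),
    )


def _persist(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(result.report.to_json())
    np.savetxt(outdir / "correlation.csv", result.correlation.rho, delimiter=",")
    coords = result.embedding.coords
    with open(outdir / "embedding.csv", "w") as fh:
        fh.write("cone_id,dim1,dim2,dim3\n")
        for i, (a, b, c) in enumerate(coords):
            fh.write(f"{i},{a!r},{b!r},{c!r}\n")
    with open(outdir / "flattened.csv", "w") as fh:
        fh.write("cone_id,flat_lambda\n")
        for i, v in zip(result.flattened.cone_indices, result.flattened.values):
            fh.write(f"{i},{v!r}\n")
    with open(outdir / "labels.csv", "w") as fh:
        fh.write("cone_id,label\n")
        for i, lab in enumerate(result.classifier.labels_):
            fh.write(f"{i},{lab}\n")
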