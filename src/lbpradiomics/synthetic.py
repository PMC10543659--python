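"""Seeded phantom cohorts with a planted micro-texture contrast.

Each phantom slice is a smooth elliptical "brain" on a dark background.
For the patient class, a high-frequency binary speckle texture is blended
into a small disc (a deep-brain focus) at weight ``delta``; controls get no
speckle. Speckle raises local edge density, which the riu2 LBP codes 4..7
of an 8-bit group respond to, so the planted contrast is visible to the
descriptor but — at moderate ``delta`` — subtle to the eye, emulating the
minute local-appearance differences the pipeline is meant to detect.

``delta = 0`` makes the two classes exchangeable in distribution. All
randomness flows from one root seed through ``numpy.random.SeedSequence``
spawned per (class, subject, slice), so cohorts are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["PhantomSpec", "generate_slice", "generate_subject_stack", "generate_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a two-class phantom cohort.

    delta is the blend weight of the planted speckle texture inside the
    lesion disc for class 1; 0 = no class difference, 1 = pure speckle.
    """

    n_per_class: int = 20
    side: int = 180
    n_slices: int = 5
    background_sigma: float = 6.0  # Gaussian blur of the background field, px
    lesion_center: tuple[int, int] = (90, 90)
    lesion_radius: int = 24  # px
    delta: float = 0.5
    noise_sd: float = 2.0  # additive Gaussian noise, intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.side < 8 or self.n_slices < 1 or self.n_per_class < 0:
            raise ValueError("invalid phantom dimensions")
        r, c = self.lesion_center
        rad = self.lesion_radius
        if r - rad < 0 or c - rad < 0 or r + rad >= self.side or c + rad >= self.side:
            raise ValueError("lesion disc extends outside the image")


# intensity range of the smoothed brain field and of the binary speckle
_BG_LO, _BG_HI = 30.0, 220.0
_SPECKLE_LO, _SPECKLE_HI = 40.0, 200.0


def _rng(spec: PhantomSpec, class_label: int, subject: int, slice_index: int):
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, class_label, subject, slice_index])
    )


def _masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    s = spec.side
    rr, cc = np.mgrid[0:s, 0:s]
    cy = cx = (s - 1) / 2.0
    brain = ((rr - cy) / (0.42 * s)) ** 2 + ((cc - cx) / (0.36 * s)) ** 2 <= 1.0
    lr, lc = spec.lesion_center
    lesion = (rr - lr) ** 2 + (cc - lc) ** 2 <= spec.lesion_radius**2
    return brain, lesion


def generate_slice(
    spec: PhantomSpec, class_label: int, subject_index: int, slice_index: int
) -> np.ndarray:
    """One deterministic phantom slice for (seed, class, subject, slice)."""
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 (control) or 1 (patient)")
    rng = _rng(spec, class_label, subject_index, slice_index)
    brain, lesion = _masks(spec)

    field = ndimage.gaussian_filter(
        rng.normal(size=(spec.side, spec.side)), spec.background_sigma
    )
    lo, hi = field.min(), field.max()
    img = _BG_LO + (field - lo) / (hi - lo + 1e-12) * (_BG_HI - _BG_LO)
    img = np.where(brain, img, 0.0)

    # speckle is drawn for both classes (keeps the rng stream aligned) but
    # only blended for patients, at weight delta
    speckle = np.where(
        rng.random((spec.side, spec.side)) < 0.5, _SPECKLE_HI, _SPECKLE_LO
    )
    if class_label == 1 and spec.delta > 0:
        blend = lesion & brain
        img[blend] = (1.0 - spec.delta) * img[blend] + spec.delta * speckle[blend]

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return img


def generate_subject_stack(
    spec: PhantomSpec, class_label: int, subject_index: int
) -> np.ndarray:
    """All slices of one subject as a (side, side, n_slices) array."""
    return np.stack(
        [
            generate_slice(spec, class_label, subject_index, k)
            for k in range(spec.n_slices)
        ],
        axis=-1,
    )


def generate_cohort(spec: PhantomSpec, out_dir) -> pd.DataFrame:
    """Write per-subject NIfTI volumes and a manifest CSV; return the manifest.

    Volumes are (side, side, n_slices); the manifest has columns
    subject_id, path, modality, label and round-trips through
    :func:`lbpradiomics.preprocess.load_volume` / ``load_manifest``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for label in (0, 1):
        for subj in range(spec.n_per_class):
            stack = generate_subject_stack(spec, label, subj)
            sid = f"{'pd' if label else 'hc'}{subj:03d}"
            path = out_dir / f"{sid}.nii"
            # save transposed so load_volume's in-plane transpose restores it
            nib.save(
                nib.Nifti1Image(
                    np.transpose(stack, (1, 0, 2)).astype(np.float32), np.eye(4)
                ),
                str(path),
            )
            rows.append(
                {"subject_id": sid, "path": str(path), "modality": "T1", "label": label}
            )
    manifest = pd.DataFrame(rows, columns=["subject_id", "path", "modality", "label"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def with_delta(spec: PhantomSpec, delta: float) -> PhantomSpec:
    """Copy of a spec with a different planted contrast."""
    return replace(spec, delta=delta)
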