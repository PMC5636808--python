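"""Reading and writing diffusion volumes, gradient tables and run configs.

Subject data are 4D NIfTI images (one scalar volume per gradient direction)
with FSL-style ``bvec`` (3 rows) / ``bval`` (1 row) text files.  Inputs are
assumed co-registered with the gradient frame equal to the image frame.
Volumes with ``b`` below 50 s/mm^2 are treated as baseline images and excluded
from the shell.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml

from .fusion import FusionConfig, TemplateVolume
from .gradients import GradientScheme
from .synthetic import PopulationDataset, SimulationConfig

__all__ = [
    "SubjectRecord",
    "RunConfig",
    "read_gradient_table",
    "write_gradient_table",
    "read_population",
    "write_population",
    "write_template",
]

logger = logging.getLogger(__name__)

B0_THRESHOLD = 50.0  # s/mm^2


@dataclasses.dataclass(frozen=True)
class SubjectRecord:
    """Paths of one subject's image and gradient table."""

    image: pathlib.Path
    bvec: pathlib.Path
    bval: pathlib.Path
    subject_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "image", pathlib.Path(self.image))
        object.__setattr__(self, "bvec", pathlib.Path(self.bvec))
        object.__setattr__(self, "bval", pathlib.Path(self.bval))


def read_gradient_table(bvec_path, bval_path) -> tuple[np.ndarray, np.ndarray]:
    """FSL gradient table: returns (directions (K, 3), bvals (K,))."""
    bvecs = np.loadtxt(bvec_path)
    bvals = np.atleast_1d(np.loadtxt(bval_path))
    if bvecs.shape[0] != 3:
        raise ValueError("bvec file must have 3 rows")
    if bvecs.shape[1] != bvals.shape[0]:
        raise ValueError("bvec and bval entry counts differ")
    dirs = bvecs.T.astype(float)
    norms = np.linalg.norm(dirs, axis=1)
    nonzero = norms > 0
    dirs[nonzero] /= norms[nonzero, None]
    return dirs, bvals.astype(float)


def write_gradient_table(scheme: GradientScheme, bvec_path, bval_path) -> None:
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.10f")
    np.savetxt(bval_path, np.full((1, scheme.count), scheme.b_value), fmt="%.1f")


def read_population(records: Sequence[SubjectRecord]) -> PopulationDataset:
    """Assemble a population dataset from per-subject NIfTI + bvec/bval files.

    All subjects must share one scheme (per-axis agreement within 1e-6);
    baseline volumes (b < 50 s/mm^2) are dropped from the shell with a log note.
    """
    if not records:
        raise ValueError("no subject records given")
    signals = []
    scheme: GradientScheme | None = None
    grid_shape: tuple[int, int, int] | None = None
    for rec in records:
        dirs, bvals = read_gradient_table(rec.bvec, rec.bval)
        shell = bvals >= B0_THRESHOLD
        if not np.all(shell):
            logger.info(
                "subject %s: excluding %d baseline volume(s) with b < %g",
                rec.subject_id or rec.image.name, int(np.sum(~shell)), B0_THRESHOLD,
            )
        dirs, bvals = dirs[shell], bvals[shell]
        img = nib.load(str(rec.image))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"subject {rec.subject_id or rec.image}: image is not 4D")
        if data.shape[3] != len(shell):
            raise ValueError(
                f"subject {rec.subject_id or rec.image}: image has {data.shape[3]} "
                f"volumes but the gradient table lists {len(shell)} entries"
            )
        data = data[..., shell]
        subj_scheme = GradientScheme(dirs, float(np.median(bvals)))
        if scheme is None:
            scheme, grid_shape = subj_scheme, data.shape[:3]
        else:
            if data.shape[:3] != grid_shape:
                raise ValueError(f"subject {rec.subject_id or rec.image}: grid shape mismatch")
            if not np.allclose(
                np.abs(np.sum(subj_scheme.directions * scheme.directions, axis=1)), 1.0,
                atol=1e-6,
            ):
                raise ValueError(
                    f"subject {rec.subject_id or rec.image}: gradient scheme "
                    "differs from the first subject's"
                )
        signals.append(data.reshape(-1, scheme.count))
    return PopulationDataset(
        signals=np.clip(np.stack(signals), 0.0, None),
        scheme=scheme,
        grid_shape=tuple(int(s) for s in grid_shape),
    )


def write_population(
    population: PopulationDataset, outdir, prefix: str = "subject"
) -> list[SubjectRecord]:
    """Write one 4D NIfTI per subject plus shared bvec/bval, ground truth and sidecar."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = population.scheme
    bvec, bval = outdir / f"{prefix}.bvec", outdir / f"{prefix}.bval"
    write_gradient_table(scheme, bvec, bval)
    shape = population.grid_shape + (scheme.count,)
    records = []
    for d in range(population.n_subjects):
        path = outdir / f"{prefix}_{d:03d}.nii"
        nib.save(nib.Nifti1Image(population.signals[d].reshape(shape), np.eye(4)), str(path))
        records.append(SubjectRecord(path, bvec, bval, subject_id=f"{prefix}_{d:03d}"))
    if population.ground_truth is not None:
        nib.save(
            nib.Nifti1Image(population.ground_truth.reshape(shape), np.eye(4)),
            str(outdir / f"{prefix}_ground_truth.nii"),
        )
    sidecar = {
        "sigma": population.sigma,
        "meta": population.meta,
        "true_axes": None
        if population.true_axes is None
        else np.asarray(population.true_axes).tolist(),
    }
    (outdir / f"{prefix}_info.json").write_text(json.dumps(sidecar, indent=2))
    return records


def write_template(
    template: TemplateVolume,
    path_prefix,
    config: "RunConfig | FusionConfig | None" = None,
    sigma: float | None = None,
) -> dict:
    """Write a fused template: 4D NIfTI + bvec/bval + JSON convergence report."""
    if not np.all(np.isfinite(template.signals)):
        raise ValueError("template contains non-finite values")
    prefix = pathlib.Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    nib.save(
        nib.Nifti1Image(template.volume(), np.eye(4)), str(prefix.with_suffix(".nii"))
    )
    write_gradient_table(
        template.scheme, prefix.parent / (prefix.name + ".bvec"),
        prefix.parent / (prefix.name + ".bval"),
    )
    report = {
        "method": template.method,
        "iterations_used": template.iterations_used,
        "trace": [float(t) for t in template.trace],
        "config": dataclasses.asdict(config) if dataclasses.is_dataclass(config) else config,
    }
    if sigma is not None:
        report["sigma"] = sigma
        gamma = getattr(config, "gamma", None) if config is not None else None
        if gamma is not None:
            report["stop_threshold"] = gamma * sigma
    (prefix.parent / (prefix.name + "_report.json")).write_text(json.dumps(report, indent=2))
    return report


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Union of simulation, fusion and evaluation settings with provenance."""

    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    fusion: FusionConfig = dataclasses.field(default_factory=FusionConfig)
    peak_relative_threshold: float = 0.4
    peak_min_separation: float = 25.0
    peak_max_peaks: int = 3
    seed: int = 0

    def to_yaml(self, path) -> None:
        doc = {
            "simulation": dataclasses.asdict(self.simulation),
            "fusion": dataclasses.asdict(self.fusion),
            "evaluation": {
                "peak_relative_threshold": self.peak_relative_threshold,
                "peak_min_separation": self.peak_min_separation,
                "peak_max_peaks": self.peak_max_peaks,
            },
            "seed": self.seed,
        }
        doc["simulation"]["grid_shape"] = list(self.simulation.grid_shape)
        pathlib.Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(pathlib.Path(path).read_text())
        sim = doc.get("simulation", {})
        if "grid_shape" in sim:
            sim["grid_shape"] = tuple(sim["grid_shape"])
        ev = doc.get("evaluation", {})
        return cls(
            simulation=SimulationConfig(**sim),
            fusion=FusionConfig(**doc.get("fusion", {})),
            peak_relative_threshold=ev.get("peak_relative_threshold", 0.4),
            peak_min_separation=ev.get("peak_min_separation", 25.0),
            peak_max_peaks=ev.get("peak_max_peaks", 3),
            seed=doc.get("seed", 0),
        )
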