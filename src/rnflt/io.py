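"""Text-based readers/writers and run configuration.

Formats are deliberately plain so any toolchain can produce or consume
them:

* **Maps/masks** — whitespace-delimited text grids (one map row per
  line, '.' decimal, UTF-8) with a JSON sidecar carrying metadata
  (patient/eye ids, laterality, date, pixel pitch, signal strength).
  Masks use 0/1 entries and round-trip bit-exactly.
* **VF series** — CSV with columns ``date, md, vfi, td_1..td_52, fl,
  fp, fn``.
* **Cohorts** — a directory with ``manifest.csv`` plus per-eye map,
  disc-mask, optional donor-map, and VF files.
* **Config** — a single YAML document of defaults that command-line
  flags override.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from .maps import ArtifactMask, DiscMask, RNFLTMap
from .model import LossConfig, ModelConfig, TrainConfig
from .synthetic import (
    ArtifactModelParams,
    Cohort,
    EyeRecord,
    MapModelParams,
    StructureFunctionLink,
    VFSimParams,
)
from .vf import VFExam, VFSeries

_GRID_FMT = "%.17g"   # full double precision -> bitwise round trips


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

def _read_grid(path: Path, expect_cols: Optional[int] = None) -> np.ndarray:
    rows = []
    width = expect_cols
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise ParseError(
                    f"{path}:{lineno}: expected {width} columns, got {len(parts)}"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric entry ({exc})")
    if not rows:
        raise ParseError(f"{path}: empty grid")
    return np.array(rows)


def write_map(rnflt_map: RNFLTMap, path: str | Path) -> None:
    """Write a map as a text grid plus a JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, rnflt_map.values, fmt=_GRID_FMT)
    meta = {
        "patient_id": rnflt_map.patient_id,
        "eye_id": rnflt_map.eye_id,
        "laterality": rnflt_map.laterality,
        "date": rnflt_map.acquisition_date.isoformat()
        if rnflt_map.acquisition_date
        else None,
        "pixel_pitch": rnflt_map.pixel_pitch,
        "signal_strength": rnflt_map.signal_strength,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_map(path: str | Path) -> RNFLTMap:
    """Read a text-grid map; missing sidecar falls back to defaults."""
    path = Path(path)
    values = _read_grid(path)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return RNFLTMap(
        values=values,
        pixel_pitch=meta.get("pixel_pitch", 0.03),
        patient_id=meta.get("patient_id", ""),
        eye_id=meta.get("eye_id", ""),
        laterality=meta.get("laterality", "OD"),
        acquisition_date=date.fromisoformat(meta["date"]) if meta.get("date") else None,
        signal_strength=meta.get("signal_strength"),
    )


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d")


def read_mask(path: str | Path) -> np.ndarray:
    return _read_grid(Path(path)) > 0.5


# ---------------------------------------------------------------------------
# VF series
# ---------------------------------------------------------------------------

_TD_COLS = [f"td_{j + 1}" for j in range(52)]


def vf_series_to_frame(series: VFSeries) -> pd.DataFrame:
    rows = []
    for e in series.exams:
        row = {"date": e.exam_date.isoformat(), "md": e.md, "vfi": e.vfi}
        row.update({c: v for c, v in zip(_TD_COLS, e.td)})
        row.update(fl=e.fixation_loss, fp=e.false_pos, fn=e.false_neg)
        rows.append(row)
    return pd.DataFrame(rows)


def write_vf_series(series: VFSeries, path: str | Path) -> None:
    vf_series_to_frame(series).to_csv(path, index=False)


def read_vf_series(path: str | Path, eye_id: str = "") -> VFSeries:
    df = pd.read_csv(path)
    exams = [
        VFExam(
            exam_date=datetime.fromisoformat(str(r["date"])).date(),
            md=float(r["md"]),
            vfi=float(r["vfi"]),
            td=r[_TD_COLS].to_numpy(dtype=float),
            fixation_loss=float(r["fl"]),
            false_pos=float(r["fp"]),
            false_neg=float(r["fn"]),
        )
        for _, r in df.iterrows()
    ]
    return VFSeries(eye_id=eye_id, exams=exams)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    for sub in ("maps", "discs", "donors", "vf"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for e in cohort.eyes:
        write_map(e.rnflt_map, out / "maps" / f"{e.eye_id}.txt")
        write_mask(e.disc.mask, out / "discs" / f"{e.eye_id}.txt")
        if e.donor_map is not None:
            write_map(e.donor_map, out / "donors" / f"{e.eye_id}.txt")
        write_vf_series(e.vf, out / "vf" / f"{e.eye_id}.csv")
    manifest = cohort.manifest()
    manifest.insert(0, "cohort_seed", cohort.seed)
    manifest.to_csv(out / "manifest.csv", index=False)


def read_cohort(in_dir: str | Path) -> Cohort:
    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.csv")
    eyes = []
    for _, r in manifest.iterrows():
        eye_id = r["eye_id"]
        donor_path = src / "donors" / f"{eye_id}.txt"
        eyes.append(
            EyeRecord(
                patient_id=r["patient_id"],
                eye_id=eye_id,
                laterality=r["laterality"],
                severity=float(r["severity"]),
                rnflt_map=read_map(src / "maps" / f"{eye_id}.txt"),
                disc=DiscMask(read_mask(src / "discs" / f"{eye_id}.txt")),
                vf=read_vf_series(src / "vf" / f"{eye_id}.csv", eye_id=eye_id),
                mean_circle_um=float(r["mean_circle_um"]),
                donor_map=read_map(donor_path) if donor_path.exists() else None,
                donor_ar=float(r["donor_ar"]) if np.isfinite(r["donor_ar"]) else None,
            )
        )
    seed = int(manifest["cohort_seed"].iloc[0]) if "cohort_seed" in manifest else 0
    return Cohort(eyes=eyes, seed=seed)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One schema holding every tunable parameter with its default.

    Serialized as a single YAML document; CLI flags override file
    values. Every random operation takes its seed from here so a run
    log (config snapshot) fully reproduces the run.
    """

    seed: int = 0
    floor_um: float = 50.0
    map_params: MapModelParams = field(default_factory=MapModelParams)
    artifact_params: ArtifactModelParams = field(default_factory=ArtifactModelParams)
    vf_params: VFSimParams = field(default_factory=VFSimParams)
    sf_link: StructureFunctionLink = field(default_factory=StructureFunctionLink)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    cv_folds: int = 3
    bootstrap_n: int = 1000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["vf_params"]["start_date"] = self.vf_params.start_date.isoformat()
        for key in ("td_slopes", "td_intercepts"):
            v = d["vf_params"][key]
            if v is not None:
                d["vf_params"][key] = [float(x) for x in np.asarray(v)]
        d["map_params"]["shape"] = list(self.map_params.shape)
        d["artifact_params"]["fill_range"] = list(self.artifact_params.fill_range)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        if "map_params" in kwargs:
            mp = dict(kwargs["map_params"])
            if "shape" in mp:
                mp["shape"] = tuple(mp["shape"])
            kwargs["map_params"] = MapModelParams(**mp)
        if "artifact_params" in kwargs:
            ap = dict(kwargs["artifact_params"])
            if "fill_range" in ap:
                ap["fill_range"] = tuple(ap["fill_range"])
            kwargs["artifact_params"] = ArtifactModelParams(**ap)
        if "vf_params" in kwargs:
            vp = dict(kwargs["vf_params"])
            if isinstance(vp.get("start_date"), str):
                vp["start_date"] = date.fromisoformat(vp["start_date"])
            kwargs["vf_params"] = VFSimParams(**vp)
        if "sf_link" in kwargs:
            kwargs["sf_link"] = StructureFunctionLink(**kwargs["sf_link"])
        if "model" in kwargs:
            kwargs["model"] = ModelConfig(**kwargs["model"])
        if "train" in kwargs:
            tr = dict(kwargs["train"])
            if "loss" in tr:
                tr["loss"] = LossConfig(**tr["loss"])
            kwargs["train"] = TrainConfig(**tr)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# ---------------------------------------------------------------------------
# training-pair manifests
# ---------------------------------------------------------------------------

def write_pairs(pairs, patient_ids, out_dir: str | Path) -> None:
    """Write pseudo-artifact training pairs as text grids + a manifest."""
    from .pseudo import TrainingPair  # noqa: F401  (type reference)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (pair, pid) in enumerate(zip(pairs, patient_ids)):
        stem = f"pair{i:05d}"
        write_map(pair.input_map, out / f"{stem}_input.txt")
        write_map(pair.target_map, out / f"{stem}_target.txt")
        write_mask(pair.pseudo_mask.mask, out / f"{stem}_mask.txt")
        write_mask(pair.disc.mask, out / f"{stem}_disc.txt")
        rows.append({"pair": i, "stem": stem, "patient_id": pid,
                     "floor_um": pair.pseudo_mask.floor_um})
    pd.DataFrame(rows).to_csv(out / "pairs.csv", index=False)


def read_pairs(in_dir: str | Path):
    """Read pairs written by :func:`write_pairs`; returns (pairs, patient_ids)."""
    from .pseudo import TrainingPair

    src = Path(in_dir)
    manifest = pd.read_csv(src / "pairs.csv")
    pairs, pids = [], []
    for _, r in manifest.iterrows():
        stem = r["stem"]
        pairs.append(
            TrainingPair(
                input_map=read_map(src / f"{stem}_input.txt"),
                target_map=read_map(src / f"{stem}_target.txt"),
                pseudo_mask=ArtifactMask(read_mask(src / f"{stem}_mask.txt"),
                                         floor_um=float(r["floor_um"])),
                disc=DiscMask(read_mask(src / f"{stem}_disc.txt")),
            )
        )
        pids.append(r["patient_id"])
    return pairs, pids
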