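"""Reading and writing the pipeline's on-disk formats.

Event, behavior, and metabolite tables are tab-delimited text; BOLD arrays
go to ``.npz`` containers (with TR and ROI metadata), with optional NIfTI
export through nibabel for interoperability with neuroimaging tools.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .design import MemoryTestTrial, TrialSequence
from .stats import BehavioralRecord
from .synth import MetaboliteMeasurement, SyntheticSubject, VoxelTimeSeries


def save_bold(ts: VoxelTimeSeries, path) -> None:
    np.savez(path, data=ts.data, tr=ts.tr, roi_label=ts.roi_label)


def load_bold(path) -> VoxelTimeSeries:
    with np.load(path, allow_pickle=False) as z:
        return VoxelTimeSeries(
            data=z["data"], tr=float(z["tr"]), roi_label=str(z["roi_label"])
        )


def bold_to_nifti(ts: VoxelTimeSeries, path) -> None:
    """Optional NIfTI export: voxels along the first axis, time along the
    fourth; the TR is stored in the time zoom."""
    import nibabel as nib

    img = nib.Nifti1Image(
        ts.data[:, None, None, :].astype(np.float32), affine=np.eye(4)
    )
    img.header.set_zooms((1.0, 1.0, 1.0, ts.tr))
    img.header["descrip"] = ts.roi_label.encode()[:79]
    nib.save(img, str(path))


def bold_from_nifti(path, roi_label: str = "") -> VoxelTimeSeries:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)[:, 0, 0, :].astype(float)
    tr = float(img.header.get_zooms()[3])
    label = roi_label or img.header["descrip"].item().decode(errors="ignore")
    return VoxelTimeSeries(data=data, tr=tr, roi_label=label)


def write_behavior_tsv(records: Sequence[BehavioralRecord], path) -> None:
    rows = []
    for r in records:
        t = r.trial
        rows.append(
            {
                "probe": t.probe,
                "context": r.context,
                "options": "/".join(str(o) for o in t.options),
                "correct_option": t.correct_option,
                "foil_option": "" if t.foil_option is None else t.foil_option,
                "is_foil_trial": t.is_foil_trial,
                "response": r.response,
                "correct": r.correct,
                "error_kind": r.error_kind,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_behavior_tsv(path) -> List[BehavioralRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"probe", "context", "options", "correct_option", "response", "correct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"behavior table missing required columns: {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        foil = r.get("foil_option", "")
        foil = None if (pd.isna(foil) or foil == "") else int(foil)
        trial = MemoryTestTrial(
            probe=int(r["probe"]),
            context=str(r["context"]),
            options=tuple(int(x) for x in str(r["options"]).split("/")),
            correct_option=int(r["correct_option"]),
            foil_option=foil,
            is_foil_trial=bool(r.get("is_foil_trial", foil is not None)),
        )
        out.append(
            BehavioralRecord(
                trial=trial,
                response=int(r["response"]),
                correct=bool(r["correct"]),
                error_kind=str(r.get("error_kind", "")),
                context=str(r["context"]),
            )
        )
    return out


def write_mrs_tsv(measurements: Sequence[MetaboliteMeasurement], path) -> None:
    pd.DataFrame([dataclasses.asdict(m) for m in measurements]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_mrs_tsv(path) -> List[MetaboliteMeasurement]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"timepoint", "metabolite", "ratio", "crlb", "fwhm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MRS table missing required columns: {sorted(missing)}")
    return [
        MetaboliteMeasurement(
            timepoint=str(r.timepoint),
            metabolite=str(r.metabolite),
            ratio=float(r.ratio),
            crlb=float(r.crlb),
            fwhm=float(r.fwhm),
        )
        for r in df.itertuples()
    ]


def write_subject_dir(subject: SyntheticSubject, outdir, nifti: bool = False) -> Path:
    """Write one subject's events, BOLD, behavior, metabolites, and truth."""
    out = Path(outdir) / f"sub-{subject.subject_id:02d}"
    out.mkdir(parents=True, exist_ok=True)
    for b, seq in subject.events.items():
        seq.write_tsv(out / f"events_block{b}.tsv")
    for (roi, b), ts in subject.bold.items():
        save_bold(ts, out / f"bold_{roi}_block{b}.npz")
        if nifti:
            bold_to_nifti(ts, out / f"bold_{roi}_block{b}.nii.gz")
    write_behavior_tsv(subject.behavior.records, out / "behavior.tsv")
    write_mrs_tsv(subject.mrs, out / "mrs.tsv")
    truth = dataclasses.asdict(subject.truth)
    truth["gaba_inestimable"] = subject.gaba_inestimable
    truth["scan_accuracy"] = list(subject.behavior.scan_accuracy)
    truth["ring1_order"] = list(subject.rings[0].order)
    truth["ring2_order"] = list(subject.rings[1].order)
    truth["training_block_accuracy"] = subject.behavior.training_block_accuracy
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    subject.tax.write_tsv(out / "taxonomy.tsv")
    return out


def read_subject_dir(path) -> SyntheticSubject:
    """Reconstruct a subject from a directory written by
    :func:`write_subject_dir` (or externally provided in the same layout)."""
    import dataclasses as dc

    from .design import DesignParams, TrialSequence
    from .rings import CONTEXTS, RingStructure, link_taxonomy
    from .synth import BehaviorData, GroundTruth

    path = Path(path)
    meta = json.loads((path / "truth.json").read_text())
    ring1 = RingStructure(order=tuple(meta.pop("ring1_order")), context=CONTEXTS[0])
    ring2 = RingStructure(order=tuple(meta.pop("ring2_order")), context=CONTEXTS[1])
    gaba_inestimable = bool(meta.pop("gaba_inestimable", False))
    scan_accuracy = tuple(meta.pop("scan_accuracy", (1.0, 1.0)))
    block_acc = {
        k: [float(x) for x in v]
        for k, v in meta.pop("training_block_accuracy", {}).items()
    }
    known = {f.name for f in dc.fields(GroundTruth)}
    truth = GroundTruth(**{k: v for k, v in meta.items() if k in known})

    events = {}
    for b in (1, 2):
        f = path / f"events_block{b}.tsv"
        if f.exists():
            events[b] = TrialSequence.read_tsv(f, params=DesignParams())
            events[b].block = b
    bold = {}
    for f in sorted(path.glob("bold_*.npz")):
        _, roi, block_tag = f.stem.split("_")
        bold[(roi, int(block_tag.removeprefix("block")))] = load_bold(f)
    records = read_behavior_tsv(path / "behavior.tsv")
    behavior = BehaviorData(
        training_block_accuracy=block_acc,
        training_assoc_accuracy={},
        learning_accuracy={k: max(v) for k, v in block_acc.items() if v},
        records=records,
        scan_accuracy=scan_accuracy,
    )
    sid = int(path.name.split("-")[-1]) if "-" in path.name else 0
    return SyntheticSubject(
        subject_id=sid,
        seed=(),
        truth=truth,
        rings=(ring1, ring2),
        tax=link_taxonomy(ring1, ring2),
        events=events,
        bold=bold,
        behavior=behavior,
        mrs=read_mrs_tsv(path / "mrs.tsv"),
        gaba_inestimable=gaba_inestimable,
    )


def read_cohort_dir(path) -> List[SyntheticSubject]:
    """Read every ``sub-*`` directory under ``path``."""
    subdirs = sorted(Path(path).glob("sub-*"))
    if not subdirs:
        raise ValueError(f"no sub-* directories under {path}")
    return [read_subject_dir(d) for d in subdirs]
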