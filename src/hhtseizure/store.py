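"""On-disk layout for patient datasets.

A dataset directory holds one ASCII sample matrix per record
(``preictal_<k>.txt``, ``interictal_<j>.txt``) plus a ``manifest.json``
with the sampling rate, channel roles, seizure onsets, artifact
annotations and the leave-one-seizure-out splits, so the exact train/test
partition travels with the data.
"""

from __future__ import annotations

import json
from pathlib import Path

from .io import EEGRecord, read_ascii_record, write_ascii_record
from .synthetic import Split, SynthParams, SynthPatient

__all__ = ["save_patient", "load_patient"]


def save_patient(patient: SynthPatient, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for k, rec in enumerate(patient.preictal):
        write_ascii_record(rec, d / f"preictal_{k}.txt")
    for j, rec in enumerate(patient.interictal):
        write_ascii_record(rec, d / f"interictal_{j}.txt")
    ref = patient.preictal[0]
    manifest = {
        "fs": ref.fs,
        "channel_roles": list(ref.channel_roles),
        "n_preictal": len(patient.preictal),
        "n_interictal": len(patient.interictal),
        "onsets": [r.seizure_onsets for r in patient.preictal],
        "artifacts": {
            f"preictal_{k}": patient.preictal[k].artifacts
            for k in range(len(patient.preictal))
        }
        | {
            f"interictal_{j}": patient.interictal[j].artifacts
            for j in range(len(patient.interictal))
        },
        "splits": [
            {
                "test_seizure": s.test_seizure,
                "test_interictal": s.test_interictal,
                "train_seizures": s.train_seizures,
                "train_interictal": s.train_interictal,
            }
            for s in patient.splits
        ],
        "seed": patient.seed,
        "gamma_boost": patient.params.gamma_boost,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_patient(directory) -> SynthPatient:
    d = Path(directory)
    man = json.loads((d / "manifest.json").read_text())
    roles = tuple(man["channel_roles"])
    fs = man["fs"]

    def _load(name, onsets) -> EEGRecord:
        rec = read_ascii_record(
            d / f"{name}.txt",
            fs=fs,
            channel_roles=roles,
            n_channels=len(roles),
            artifacts=[tuple(a) for a in man["artifacts"].get(name, [])],
            seizure_onsets=onsets,
        )
        return rec

    preictal = [
        _load(f"preictal_{k}", list(man["onsets"][k]))
        for k in range(man["n_preictal"])
    ]
    interictal = [
        _load(f"interictal_{j}", []) for j in range(man["n_interictal"])
    ]
    splits = [
        Split(
            test_seizure=s["test_seizure"],
            test_interictal=list(s["test_interictal"]),
            train_seizures=list(s["train_seizures"]),
            train_interictal=list(s["train_interictal"]),
        )
        for s in man["splits"]
    ]
    return SynthPatient(
        preictal=preictal,
        interictal=interictal,
        splits=splits,
        params=SynthParams(gamma_boost=man.get("gamma_boost", 2.0)),
        seed=man.get("seed", 0),
    )
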