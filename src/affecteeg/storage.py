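"""HDF5 persistence for corpora and cohorts, CSV for score tables.

Layout of a corpus file::

    /                       attrs: sampling_rate, seed, params (JSON), schema
    /subjects/s01/t00       dataset (n_channels, n_samples), attrs valence, arousal
    ...

Cohort files hold one dataset per participant with the latents and group as
attributes.  Signals are stored float32; attributes make every file
self-describing enough to reload without the generating code's state.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .synthetic import (
    CohortRecording,
    DeapLikeCorpus,
    GeneratorParams,
    SubjectRecord,
    TrialRecord,
)

SCHEMA_VERSION = 1

__all__ = ["save_corpus", "load_corpus", "save_cohort", "load_cohort"]


def _params_to_json(params: GeneratorParams) -> str:
    d = dataclasses.asdict(params)
    d["band_base_sd"] = dict(d["band_base_sd"])
    return json.dumps(d)


def _params_from_json(s: str) -> GeneratorParams:
    d = json.loads(s)
    for key in ("valence_channels", "arousal_channels"):
        if key in d:
            d[key] = tuple(d[key])
    return GeneratorParams(**d)


def save_corpus(corpus: DeapLikeCorpus, path) -> None:
    with h5py.File(Path(path), "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        f.attrs["sampling_rate"] = corpus.sampling_rate
        f.attrs["seed"] = corpus.seed
        f.attrs["params"] = _params_to_json(corpus.params)
        g = f.create_group("subjects")
        for subj in corpus.subjects:
            sg = g.create_group(subj.subject_id)
            for ti, trial in enumerate(subj.trials):
                ds = sg.create_dataset(f"t{ti:02d}", data=trial.signal.astype(np.float32))
                ds.attrs["valence"] = trial.valence
                ds.attrs["arousal"] = trial.arousal


def load_corpus(path) -> DeapLikeCorpus:
    with h5py.File(Path(path), "r") as f:
        params = _params_from_json(f.attrs["params"])
        subjects = []
        for sid in sorted(f["subjects"]):
            sg = f["subjects"][sid]
            trials = [
                TrialRecord(
                    signal=sg[t][()],
                    valence=float(sg[t].attrs["valence"]),
                    arousal=float(sg[t].attrs["arousal"]),
                )
                for t in sorted(sg)
            ]
            subjects.append(SubjectRecord(subject_id=sid, trials=trials))
        return DeapLikeCorpus(
            subjects=subjects,
            sampling_rate=float(f.attrs["sampling_rate"]),
            params=params,
            seed=int(f.attrs["seed"]),
        )


def save_cohort(cohort: list[CohortRecording], path) -> None:
    with h5py.File(Path(path), "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        g = f.create_group("participants")
        for rec in cohort:
            data = rec.signal if rec.signal is not None else np.empty((0, 0), np.float32)
            ds = g.create_dataset(rec.participant_id, data=data.astype(np.float32))
            ds.attrs.update(
                group=rec.group,
                latent_valence=rec.latent_valence,
                latent_arousal=rec.latent_arousal,
                sampling_rate=rec.sampling_rate,
                epoch_seconds=rec.epoch_seconds,
                n_epochs=rec.n_epochs,
                has_signal=rec.signal is not None,
            )


def load_cohort(path) -> list[CohortRecording]:
    out = []
    with h5py.File(Path(path), "r") as f:
        for pid in sorted(f["participants"]):
            ds = f["participants"][pid]
            sig = ds[()] if ds.attrs["has_signal"] else None
            out.append(
                CohortRecording(
                    participant_id=pid,
                    group=str(ds.attrs["group"]),
                    latent_valence=float(ds.attrs["latent_valence"]),
                    latent_arousal=float(ds.attrs["latent_arousal"]),
                    sampling_rate=float(ds.attrs["sampling_rate"]),
                    epoch_seconds=float(ds.attrs["epoch_seconds"]),
                    n_epochs=int(ds.attrs["n_epochs"]),
                    signal=sig,
                )
            )
    return out
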