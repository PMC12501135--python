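"""File formats: columnar spectra with a session manifest, trial tables,
curve/feature TSVs, and NIfTI volumes."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .spectro import EditedSession, Spectrum, TissueFractions

__all__ = [
    "write_session",
    "read_session",
    "write_trials",
    "read_trials",
    "write_nifti",
    "read_nifti",
    "write_curve_tsv",
]

TRIAL_COLUMNS = ["trial", "block", "type", "responded", "rt_ms"]


def write_session(session: EditedSession, directory: str | Path) -> Path:
    """Write a session as one `ppm intensity` TSV per average plus a JSON
    manifest recording kind, pair index, TR and tissue fractions."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []

    def dump(spec: Spectrum, name: str, kind: str, pair_index: int | None):
        pd.DataFrame({"ppm": spec.ppm, "intensity": spec.intensity}).to_csv(
            directory / name, sep="\t", index=False)
        entries.append({"file": name, "kind": kind, "pair_index": pair_index})

    for i, (on, off) in enumerate(zip(session.on, session.off)):
        dump(on, f"pair{i:03d}_on.tsv", "ON", i)
        dump(off, f"pair{i:03d}_off.tsv", "OFF", i)
    dump(session.water, "water.tsv", "WATER", None)

    manifest = {
        "condition": session.condition,
        "tr_s": session.tr_s,
        "fractions": {"f_gm": session.fractions.f_gm,
                      "f_wm": session.fractions.f_wm,
                      "f_csf": session.fractions.f_csf},
        "spectra": entries,
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_session(directory: str | Path) -> EditedSession:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    on, off, water = {}, {}, None
    for entry in manifest["spectra"]:
        df = pd.read_csv(directory / entry["file"], sep="\t")
        spec = Spectrum(df["ppm"].to_numpy(), df["intensity"].to_numpy(),
                        kind=entry["kind"])
        if entry["kind"] == "ON":
            on[entry["pair_index"]] = spec
        elif entry["kind"] == "OFF":
            off[entry["pair_index"]] = spec
        else:
            water = spec
    f = manifest["fractions"]
    return EditedSession(
        condition=manifest["condition"],
        on=[on[i] for i in sorted(on)],
        off=[off[i] for i in sorted(off)],
        water=water,
        fractions=TissueFractions(f["f_gm"], f["f_wm"], f["f_csf"]),
        tr_s=manifest["tr_s"],
    )


def write_trials(trials: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    trials[TRIAL_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["responded"] = df["responded"].astype(bool)
    return df


def write_nifti(volume: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), path)
    return path


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_curve_tsv(rows: list, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
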