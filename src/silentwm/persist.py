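"""Run manifests and result export (CSV responses, HDF5 traces)."""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ModelConfig, config_to_dict


def write_manifest(path, config: ModelConfig, master_seed: int,
                   participant_seeds, design: str, extra: dict | None = None):
    """Everything needed to reproduce a run bit-for-bit."""
    manifest = {
        "version": __version__,
        "design": design,
        "master_seed": int(master_seed),
        "participant_seeds": [int(s) for s in participant_seeds],
        "config": config_to_dict(config),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest


def read_manifest(path) -> dict:
    with open(path) as f:
        return json.load(f)


def export_results(table: pd.DataFrame, out_dir, config: ModelConfig,
                   master_seed: int, participant_seeds, design: str,
                   traces: dict | None = None) -> dict:
    """Write responses.csv, manifest.json and optionally traces.h5.

    ``traces`` maps group names to dicts of arrays (e.g. decoded vectors,
    spike counts, calcium/resource means per module).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    csv_path = out / "responses.csv"
    table.to_csv(csv_path, index=False)
    paths["responses"] = csv_path
    if traces:
        import h5py

        h5_path = out / "traces.h5"
        with h5py.File(h5_path, "w") as f:
            for group, arrays in traces.items():
                g = f.create_group(group)
                for name, arr in arrays.items():
                    g.create_dataset(name, data=np.asarray(arr),
                                     compression="gzip")
        paths["traces"] = h5_path
    paths["manifest"] = out / "manifest.json"
    write_manifest(paths["manifest"], config, master_seed, participant_seeds,
                   design, extra={"n_responses": int(len(table))})
    return paths
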