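"""Plain-text writers: TSV matrices with JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


def write_matrix_tsv(path, matrix: np.ndarray,
                     columns: Optional[Sequence[str]] = None,
                     index: Optional[Sequence] = None) -> None:
    df = pd.DataFrame(np.asarray(matrix), columns=columns, index=index)
    df.to_csv(path, sep="\t", index=index is not None)


def read_matrix_tsv(path, has_index: bool = False) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0 if has_index else None)
    return df.to_numpy()


def write_json(path, obj: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def write_dataset(dataset, out_dir) -> None:
    """TSV series/truth matrices plus a JSON sidecar for a dataset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model, config = dataset.model, dataset.config
    write_matrix_tsv(out / "ground_truth_weights.tsv", model.weights)
    dataset.design.to_csv(out / "design.tsv", sep="\t", index=False)
    for p in range(config.n_participants):
        if dataset.rest_timeseries is not None:
            write_matrix_tsv(out / f"rest_p{p:03d}.tsv",
                             dataset.rest_timeseries[p])
        if dataset.task_bold:
            write_matrix_tsv(out / f"task_bold_p{p:03d}.tsv",
                             dataset.task_bold[p])
        write_matrix_tsv(out / f"truth_activations_p{p:03d}.tsv",
                         dataset.truth_activations[p])
        write_matrix_tsv(out / f"truth_flow_p{p:03d}.tsv",
                         dataset.truth_flow_component[p])
    write_json(out / "sidecar.json", {
        "config": config.to_dict(),
        "partition": model.partition,
        "complexes": {
            k: {"units": v["units"], "category": v["category"]}
            for k, v in model.complexes.items()
        },
        "v1_units": model.v1_units,
        "category_sources": {k: v for k, v in model.category_sources.items()},
        "spectral_radius": model.spectral_radius,
        "seed": config.seed,
    })
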