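"""Configuration parsing and output writers.

Outputs are plain text: tab-separated tables with a header row ('.' decimal,
UTF-8) and JSON with stable key order.  Every output directory receives a
``run_meta.json`` with the full parameters, seed and package version, enough
to reproduce the run exactly.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Dict, Iterable, Iterator, Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .params import ParameterError, SimParams
from .sim import SimOutput

__all__ = ["parse_config", "emit_config", "write_outputs", "write_tsv_stream", "write_json"]


def parse_config(path_or_dict) -> SimParams:
    """Validated simulation parameters from a YAML/JSON file or a mapping.

    Unknown keys are rejected with the offending field named.
    """
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh)
    else:
        data = dict(path_or_dict)
    if not isinstance(data, dict):
        raise ParameterError("<root>", "config must be a mapping of parameter names to values")
    return SimParams.from_dict(data)


def emit_config(params: SimParams, path: Optional[Path] = None) -> str:
    """Serialize parameters to YAML; round-trips through :func:`parse_config`."""
    text = yaml.safe_dump(params.to_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(data: Dict, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(data), fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_tsv_stream(rows: Iterable[Sequence], header: Sequence[str], path: Path) -> int:
    """Stream rows to a TSV file without materializing them in memory."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = 0
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        for row in rows:
            w.writerow(row)
            n += 1
    return n


def _trajectory_rows(out: SimOutput) -> Iterator[Sequence]:
    for mid in sorted(out.trajectories):
        t0 = out.trajectory_t0[mid]
        stride = out.params.trajectory_stride
        for i, c in enumerate(out.trajectories[mid]):
            yield (mid, t0 + i * stride, repr(c / out.params.N))


def write_outputs(out: SimOutput, out_dir: Path) -> Dict[str, Path]:
    """Write the standard output files of a simulation run.

    ``fixations.tsv`` (id, position, s, t_origin, t_fixed), ``genstats.tsv``
    (generation, mean_log_fitness, var_log_fitness, n_segregating), optional
    ``trajectories.tsv`` and ``heterozygosity.tsv``, plus ``run_meta.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["fixations"] = out_dir / "fixations.tsv"
    write_tsv_stream(
        (
            (m.id, repr(m.position), repr(m.s), m.t_origin, m.t_fate)
            for m in sorted(out.fixations, key=lambda m: (m.t_fate, m.id))
        ),
        ["id", "position", "s", "t_origin", "t_fixed"],
        paths["fixations"],
    )

    paths["genstats"] = out_dir / "genstats.tsv"
    rows = zip(
        out.generations,
        (repr(float(x)) for x in out.mean_log_fitness),
        (repr(float(x)) for x in out.var_log_fitness),
        out.n_segregating,
    )
    write_tsv_stream(rows, ["generation", "mean_log_fitness", "var_log_fitness", "n_segregating"], paths["genstats"])

    if out.trajectories:
        paths["trajectories"] = out_dir / "trajectories.tsv"
        write_tsv_stream(_trajectory_rows(out), ["mutation_id", "generation", "frequency"], paths["trajectories"])
    if out.heterozygosity is not None:
        paths["heterozygosity"] = out_dir / "heterozygosity.tsv"
        write_tsv_stream(
            zip(out.generations, (repr(float(h)) for h in out.heterozygosity)),
            ["generation", "H"],
            paths["heterozygosity"],
        )

    paths["meta"] = out_dir / "run_meta.json"
    write_json(
        {
            "params": out.params.to_dict(),
            "burn_in": out.burn_in,
            "version": __version__,
            "n_fixations": len(out.fixations),
            "n_losses": len(out.losses),
        },
        paths["meta"],
    )
    return paths
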