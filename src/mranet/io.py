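"""File formats: MIDAS-flavored perturbation-data CSV and model JSON.

The data format is a comma-separated table with one row per condition:
``ID`` (condition id), treatment columns ``TR:<node>:Stim`` and
``TR:<node>:Inhib`` holding 0/1, value columns ``DV:<readout>`` (log2 fold
change versus solvent control) and optional error columns ``DE:<readout>``
(standard error, log2 units).  Empty cells are missing.  Floats are
serialized at 9 significant digits, so round-trips are value-exact at that
precision.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from . import __version__
from .fitting import FitResult, MRAModel
from .identifiability import derive_parametrisation
from .network import (
    Condition,
    DesignError,
    PerturbationDataset,
    PerturbationDesign,
    SignalingNetwork,
)

__all__ = [
    "read_perturbation_data",
    "write_perturbation_data",
    "write_model_json",
    "read_model_json",
    "write_profile_csv",
    "write_consensus_csv",
]

_FMT = "%.9g"


def _fmt(x: float) -> str:
    return "" if not np.isfinite(x) else _FMT % x


def write_perturbation_data(
    design: PerturbationDesign,
    data: PerturbationDataset,
    path_or_buf,
) -> None:
    """Write design + dataset as a MIDAS-flavored CSV."""
    stim_nodes = design.stimulated_nodes()
    inhib_nodes = design.inhibited_nodes()
    cols: dict[str, list] = {"ID": [c.condition_id for c in design.conditions]}
    for n in stim_nodes:
        cols[f"TR:{n}:Stim"] = [int(n in c.stimulated) for c in design.conditions]
    for n in inhib_nodes:
        cols[f"TR:{n}:Inhib"] = [int(n in c.inhibited) for c in design.conditions]
    for j, ro in enumerate(design.readout_names):
        cols[f"DV:{ro}"] = [_fmt(v) for v in data.values[:, j]]
    for j, ro in enumerate(design.readout_names):
        cols[f"DE:{ro}"] = [_fmt(v) for v in data.errors[:, j]]
    pd.DataFrame(cols).to_csv(path_or_buf, index=False)


def read_perturbation_data(
    source,
    readout_nodes: dict[str, str] | None = None,
    default_errors: float | dict[str, float] | None = None,
    masked=frozenset(),
    n_replicates: int = 3,
) -> tuple[PerturbationDesign, PerturbationDataset]:
    """Parse a MIDAS-flavored CSV into a design and a dataset.

    ``readout_nodes`` maps readout names to network nodes (defaults to the
    identity).  When ``DE:`` columns are absent, ``default_errors`` (scalar
    or per-readout mapping) fills the error matrix.
    """
    df = pd.read_csv(source)
    if "ID" not in df.columns:
        raise DesignError("malformed header: missing 'ID' column")
    stim_cols, inhib_cols, dv_cols, de_cols = [], [], [], []
    for c in df.columns:
        if c == "ID":
            continue
        parts = c.split(":")
        if parts[0] == "TR" and len(parts) == 3 and parts[2] == "Stim":
            stim_cols.append((c, parts[1]))
        elif parts[0] == "TR" and len(parts) == 3 and parts[2] == "Inhib":
            inhib_cols.append((c, parts[1]))
        elif parts[0] == "DV" and len(parts) == 2:
            dv_cols.append((c, parts[1]))
        elif parts[0] == "DE" and len(parts) == 2:
            de_cols.append((c, parts[1]))
        else:
            raise DesignError(f"malformed header: unrecognized column {c!r}")
    if not dv_cols:
        raise DesignError("no DV: value columns found")
    if not stim_cols and not inhib_cols:
        raise DesignError("no TR: treatment columns found")
    conditions = []
    for _, row in df.iterrows():
        stim = frozenset(n for c, n in stim_cols if row[c] == 1)
        inhib = frozenset(n for c, n in inhib_cols if row[c] == 1)
        conditions.append(Condition(str(row["ID"]), stim, inhib))
    readout_nodes = readout_nodes or {}
    measured = tuple((ro, readout_nodes.get(ro, ro)) for _, ro in dv_cols)

    def numeric(colname):
        col = pd.to_numeric(df[colname], errors="coerce")
        raw = df[colname]
        bad = col.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise DesignError(
                f"non-numeric value {raw.iloc[i]!r} in column {colname!r}, row {i}"
            )
        return col.to_numpy(dtype=float)

    values = np.column_stack([numeric(c) for c, _ in dv_cols])
    if de_cols:
        de_map = {ro: c for c, ro in de_cols}
        errors = np.column_stack(
            [
                numeric(de_map[ro]) if ro in de_map else np.full(len(df), np.nan)
                for _, ro in dv_cols
            ]
        )
    else:
        if default_errors is None:
            raise DesignError(
                "no DE: error columns and no default_errors supplied"
            )
        if isinstance(default_errors, dict):
            errors = np.column_stack(
                [np.full(len(df), float(default_errors[ro])) for _, ro in dv_cols]
            )
        else:
            errors = np.full(values.shape, float(default_errors))
    design = PerturbationDesign(tuple(conditions), measured, frozenset(masked))
    data = PerturbationDataset(values, errors, n_replicates)
    return design, data


# ---------------------------------------------------------------------------
# model JSON


def _design_to_dict(design: PerturbationDesign) -> dict:
    return {
        "conditions": [
            {
                "id": c.condition_id,
                "stimulated": sorted(c.stimulated),
                "inhibited": sorted(c.inhibited),
            }
            for c in design.conditions
        ],
        "measured": [list(m) for m in design.measured],
        "masked": sorted(list(m) for m in design.masked),
    }


def _design_from_dict(d: dict) -> PerturbationDesign:
    return PerturbationDesign(
        tuple(
            Condition(c["id"], frozenset(c["stimulated"]), frozenset(c["inhibited"]))
            for c in d["conditions"]
        ),
        tuple(tuple(m) for m in d["measured"]),
        frozenset(tuple(m) for m in d["masked"]),
    )


def write_model_json(fit: FitResult | MRAModel, path_or_buf, extra: dict | None = None):
    """Serialize a fitted model (or a bare model) with its statistics."""
    if isinstance(fit, FitResult):
        model, stats = fit.model, {
            "wssr_fit": fit.wssr_fit,
            "n_datapoints": fit.n_datapoints,
            "n_parameters": fit.n_parameters,
            "n_free_parameters": fit.n_free_parameters,
            "reduced_chi_square": fit.reduced_chi_square,
            "n_restarts": fit.n_restarts,
            "converged_restarts": fit.converged_restarts,
            "seed": fit.seed,
        }
    else:
        model, stats = fit, None
    doc = {
        "format": "mranet-model",
        "version": __version__,
        "network": {
            "nodes": list(model.network.nodes),
            "edges": [list(e) for e in model.network.edges],
            "stimuli": sorted(model.network.stimuli),
        },
        "design": _design_to_dict(model.design),
        "raw": {s.name: float(v) for s, v in zip(model.param.symbols, model.raw)},
        "paths": [
            {
                "name": p.name,
                "exponents": {
                    model.param.symbols[j].name: int(p.exponents[j])
                    for j in p.support()
                },
                "value": model.param.path_value(p, model.raw),
            }
            for p in model.param.paths
        ],
        "fixed": dict(model.fixed),
        "statistics": stats,
    }
    if extra:
        doc.update(extra)
    text = json.dumps(doc, indent=1, sort_keys=True)
    if isinstance(path_or_buf, (str, os.PathLike)):
        with open(path_or_buf, "w") as fh:
            fh.write(text)
    else:
        path_or_buf.write(text)


def read_model_json(source) -> FitResult | MRAModel:
    """Restore a simulable model; returns a FitResult when statistics are present.

    The identifiability analysis is re-derived from the stored network and
    design and must reproduce the stored coefficient paths exactly —
    a mismatch (e.g. a hand-edited edge absent from the stored path
    support) is an error.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = json.load(source)
    if doc.get("format") != "mranet-model":
        raise ValueError("not an mranet model JSON")
    if doc.get("version") != __version__:
        import warnings

        warnings.warn(
            f"model JSON written by version {doc.get('version')}, "
            f"reading with {__version__}",
            stacklevel=2,
        )
    network = SignalingNetwork(
        tuple(doc["network"]["nodes"]),
        tuple(tuple(e) for e in doc["network"]["edges"]),
        frozenset(doc["network"]["stimuli"]),
    )
    design = _design_from_dict(doc["design"])
    param = derive_parametrisation(network, design)
    stored_names = [p["name"] for p in doc["paths"]]
    derived_names = [p.name for p in param.paths]
    if stored_names != derived_names:
        raise ValueError(
            "model JSON inconsistent: stored coefficient paths do not match "
            "the network/design (stored "
            f"{stored_names!r} vs derived {derived_names!r})"
        )
    raw_map = doc["raw"]
    try:
        raw = np.array([float(raw_map[s.name]) for s in param.symbols])
    except KeyError as exc:
        raise ValueError(f"model JSON corrupted: missing raw value {exc}") from exc
    model = MRAModel(network, design, param, raw, fixed=dict(doc.get("fixed", {})))
    stats = doc.get("statistics")
    if stats is None:
        return model
    return FitResult(
        model=model,
        wssr_fit=stats["wssr_fit"],
        n_datapoints=stats["n_datapoints"],
        n_parameters=stats["n_parameters"],
        n_free_parameters=stats["n_free_parameters"],
        reduced_chi_square=stats["reduced_chi_square"],
        n_restarts=stats["n_restarts"],
        converged_restarts=stats["converged_restarts"],
        seed=stats["seed"],
    )


# ---------------------------------------------------------------------------
# tabular reports


def write_profile_csv(profiles, path_or_buf) -> None:
    """Confidence-interval table (estimate, bounds, 'ni' markers)."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "path": p.name,
                "estimate": _FMT % p.estimate,
                "lower": "ni" if p.ni_lower else _FMT % p.lower,
                "upper": "ni" if p.ni_upper else _FMT % p.upper,
                "alpha": p.alpha,
            }
        )
    pd.DataFrame(rows).to_csv(path_or_buf, index=False)


def write_consensus_csv(consensus, path_or_buf) -> None:
    rows = []
    for e in consensus.edges:
        row = {
            "source": e.source,
            "target": e.target,
            "votes": e.votes,
            "consensus_state": e.consensus_state,
        }
        for label, state in zip(consensus.members, e.states):
            row[f"state:{label}"] = "" if state is None else state
        rows.append(row)
    pd.DataFrame(rows).to_csv(path_or_buf, index=False)
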