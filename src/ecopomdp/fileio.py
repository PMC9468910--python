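"""Reading and writing decision-process specifications.

Two dialects are supported:

* ``structured_config`` — a YAML/JSON document mirroring
  :class:`~ecopomdp.model_core.DecisionProcessSpec` field-for-field
  (``states``, ``actions``, ``observations``, ``transitions``,
  ``observation_probs``, ``returns``, ``discount``, ``horizon``,
  ``timing``, optional ``models`` block for adaptive-management model sets).
* ``pomdp_text`` — the keyword subset of the Cassandra-style ``.pomdp``
  solver format: ``discount:``, ``values:``, ``states:``, ``actions:``,
  ``observations:``, ``T:``, ``O:``, ``R:`` (with ``*`` wildcards and the
  ``identity`` / ``uniform`` matrix keywords).  ``values: cost`` negates
  returns on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .model_core import (
    DecisionProcessSpec,
    SpecValidationError,
    INFINITE,
    STANDARD,
)

__all__ = [
    "load_spec",
    "write_spec",
    "load_model_set",
    "load_projection_config",
    "ParseError",
]


class ParseError(ValueError):
    """A file failed to parse; the message names the offending line/key."""


def _sniff_format(path: Path) -> str:
    if path.suffix.lower() == ".pomdp":
        return "pomdp_text"
    return "structured_config"


def load_spec(path, format: str | None = None) -> DecisionProcessSpec:
    """Load and validate a spec from ``path``.

    ``format`` is ``"pomdp_text"`` or ``"structured_config"``; by default it
    is inferred from the file suffix (``.pomdp`` vs anything else).  An
    absent observation block yields an observable MDP.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _sniff_format(path)
    if fmt == "pomdp_text":
        return _load_pomdp_text(path)
    if fmt == "structured_config":
        return _load_config(path)
    raise ValueError(f"unknown format {format!r}")


def write_spec(spec: DecisionProcessSpec, path, format: str | None = None) -> None:
    """Write ``spec`` so that :func:`load_spec` round-trips it exactly."""
    path = Path(path)
    fmt = format or _sniff_format(path)
    if fmt == "pomdp_text":
        path.write_text(_dump_pomdp_text(spec))
    elif fmt == "structured_config":
        doc = _spec_to_dict(spec)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(doc, indent=1))
        else:
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# structured config
# ---------------------------------------------------------------------------

def _spec_to_dict(spec: DecisionProcessSpec) -> dict:
    doc: dict = {
        "states": list(spec.state_labels),
        "actions": list(spec.action_labels),
        "transitions": np.asarray(spec.transitions).tolist(),
        "returns": np.asarray(spec.returns).tolist(),
        "discount": float(spec.discount),
        "horizon": spec.horizon if spec.horizon == INFINITE else int(spec.horizon),
    }
    if spec.observation_labels is not None:
        doc["observations"] = list(spec.observation_labels)
        doc["observation_probs"] = np.asarray(spec.observations).tolist()
        doc["timing"] = spec.timing
    if spec.name:
        doc["name"] = spec.name
    return doc


def _load_config(path: Path) -> DecisionProcessSpec:
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            doc = json.loads(text)
        else:
            doc = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as e:
        raise ParseError(f"{path}: {e}") from e
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    for key in ("states", "actions", "transitions", "returns"):
        if key not in doc:
            raise ParseError(f"{path}: missing required key {key!r}")
    try:
        return DecisionProcessSpec(
            state_labels=tuple(doc["states"]),
            action_labels=tuple(doc["actions"]),
            transitions=np.asarray(doc["transitions"], dtype=float),
            returns=np.asarray(doc["returns"], dtype=float),
            discount=float(doc.get("discount", 1.0)),
            horizon=doc.get("horizon", INFINITE),
            observation_labels=(
                tuple(doc["observations"]) if "observations" in doc else None
            ),
            observations=(
                np.asarray(doc["observation_probs"], dtype=float)
                if "observation_probs" in doc
                else None
            ),
            timing=doc.get("timing", STANDARD),
            name=str(doc.get("name", "")),
        )
    except SpecValidationError:
        raise
    except (TypeError, ValueError) as e:
        raise ParseError(f"{path}: {e}") from e


# ---------------------------------------------------------------------------
# Cassandra-style .pomdp text
# ---------------------------------------------------------------------------

def _parse_names(tokens: list[str], key: str, lineno: int) -> tuple[str, ...]:
    if len(tokens) == 1 and tokens[0].isdigit():
        n = int(tokens[0])
        prefix = {"states": "s", "actions": "a", "observations": "o"}[key]
        return tuple(f"{prefix}{i}" for i in range(n))
    return tuple(tokens)


def _load_pomdp_text(path: Path) -> DecisionProcessSpec:
    lines = path.read_text().splitlines()
    # strip comments, keep line numbers
    entries: list[tuple[int, str]] = []
    for i, raw in enumerate(lines, 1):
        s = raw.split("#", 1)[0].rstrip()
        if s.strip():
            entries.append((i, s))

    header: dict = {"discount": 1.0, "values": "reward"}
    states = actions = observations = None
    t_blocks: list[tuple[int, list[str], list[list[float]]]] = []
    o_blocks: list[tuple[int, list[str], list[list[float]]]] = []
    r_entries: list[tuple[int, list[str], float]] = []

    idx = 0
    while idx < len(entries):
        lineno, line = entries[idx]
        stripped = line.strip()
        low = stripped.lower()

        def matrix_rows(start: int, nrows: int) -> tuple[list[list[float]], int]:
            rows = []
            j = start
            while j < len(entries) and len(rows) < nrows:
                ln, content = entries[j]
                word = content.strip().lower()
                if word in ("identity", "uniform"):
                    rows.append(word)  # type: ignore[arg-type]
                    j += 1
                    break
                try:
                    rows.append([float(tok) for tok in content.split()])
                except ValueError as e:
                    raise ParseError(f"{path}:{ln}: bad matrix row {content!r}") from e
                j += 1
            return rows, j

        if low.startswith("discount"):
            header["discount"] = float(stripped.split(":", 1)[1])
            idx += 1
        elif low.startswith("values"):
            header["values"] = stripped.split(":", 1)[1].strip().lower()
            idx += 1
        elif low.startswith("states"):
            states = _parse_names(stripped.split(":", 1)[1].split(), "states", lineno)
            idx += 1
        elif low.startswith("actions"):
            actions = _parse_names(stripped.split(":", 1)[1].split(), "actions", lineno)
            idx += 1
        elif low.startswith("observations"):
            observations = _parse_names(
                stripped.split(":", 1)[1].split(), "observations", lineno
            )
            idx += 1
        elif low.startswith("t") and stripped[1:].lstrip().startswith(":"):
            parts = [p.strip() for p in stripped.split(":")]
            # T: a [: s [: s' prob]]
            if len(parts) == 4:
                last = parts[3].split()
                if len(last) == 2:
                    t_blocks.append((lineno, [parts[1], parts[2], last[0]], [[float(last[1])]]))
                    idx += 1
                    continue
                raise ParseError(f"{path}:{lineno}: malformed T entry {stripped!r}")
            if len(parts) == 3:
                if states is None:
                    raise ParseError(f"{path}:{lineno}: T before states")
                rows, idx2 = matrix_rows(idx + 1, 1)
                t_blocks.append((lineno, [parts[1], parts[2]], rows))
                idx = idx2
                continue
            if len(parts) == 2:
                if states is None:
                    raise ParseError(f"{path}:{lineno}: T before states")
                rows, idx2 = matrix_rows(idx + 1, len(states))
                t_blocks.append((lineno, [parts[1]], rows))
                idx = idx2
                continue
            raise ParseError(f"{path}:{lineno}: malformed T entry {stripped!r}")
        elif low.startswith("o") and stripped[1:].lstrip().startswith(":"):
            parts = [p.strip() for p in stripped.split(":")]
            if len(parts) == 4:
                last = parts[3].split()
                if len(last) == 2:
                    o_blocks.append((lineno, [parts[1], parts[2], last[0]], [[float(last[1])]]))
                    idx += 1
                    continue
                raise ParseError(f"{path}:{lineno}: malformed O entry {stripped!r}")
            if len(parts) == 3:
                rows, idx2 = matrix_rows(idx + 1, 1)
                o_blocks.append((lineno, [parts[1], parts[2]], rows))
                idx = idx2
                continue
            if len(parts) == 2:
                if states is None:
                    raise ParseError(f"{path}:{lineno}: O before states")
                rows, idx2 = matrix_rows(idx + 1, len(states))
                o_blocks.append((lineno, [parts[1]], rows))
                idx = idx2
                continue
            raise ParseError(f"{path}:{lineno}: malformed O entry {stripped!r}")
        elif low.startswith("r") and stripped[1:].lstrip().startswith(":"):
            parts = [p.strip() for p in stripped.split(":")]
            # R: a : s : s' : o  value
            if len(parts) == 5:
                last = parts[4].split()
                if len(last) == 2:
                    r_entries.append((lineno, [parts[1], parts[2], parts[3], last[0]], float(last[1])))
                    idx += 1
                    continue
            raise ParseError(
                f"{path}:{lineno}: malformed R entry {stripped!r} "
                "(only 'R: a : s : s' : o value' is supported)"
            )
        else:
            raise ParseError(f"{path}:{lineno}: unrecognized line {stripped!r}")

    if states is None or actions is None:
        raise ParseError(f"{path}: missing states/actions declaration")
    nx, na = len(states), len(actions)
    no = len(observations) if observations else 0

    def action_ids(tok: str) -> list[int]:
        if tok == "*":
            return list(range(na))
        if tok in actions:
            return [actions.index(tok)]
        if tok.isdigit() and int(tok) < na:
            return [int(tok)]
        raise ParseError(f"{path}: unknown action {tok!r}")

    def state_ids(tok: str) -> list[int]:
        if tok == "*":
            return list(range(nx))
        if tok in states:
            return [states.index(tok)]
        if tok.isdigit() and int(tok) < nx:
            return [int(tok)]
        raise ParseError(f"{path}: unknown state {tok!r}")

    def obs_ids(tok: str) -> list[int]:
        if tok == "*":
            return list(range(no))
        if observations and tok in observations:
            return [observations.index(tok)]
        if tok.isdigit() and int(tok) < no:
            return [int(tok)]
        raise ParseError(f"{path}: unknown observation {tok!r}")

    def expand_matrix(rows, shape, lineno):
        if rows and rows[0] == "identity":
            if shape[0] != shape[1]:
                raise ParseError(f"{path}:{lineno}: identity needs a square matrix")
            return np.eye(shape[0])
        if rows and rows[0] == "uniform":
            return np.full(shape, 1.0 / shape[1])
        m = np.asarray(rows, dtype=float)
        if m.shape != shape:
            raise ParseError(f"{path}:{lineno}: matrix shape {m.shape} != {shape}")
        return m

    P = np.zeros((na, nx, nx))
    for lineno, spec_toks, rows in t_blocks:
        for a in action_ids(spec_toks[0]):
            if len(spec_toks) == 1:
                P[a] = expand_matrix(rows, (nx, nx), lineno)
            elif len(spec_toks) == 2:
                row = expand_matrix(rows, (1, nx), lineno)[0] if rows[0] not in (
                    "identity",
                    "uniform",
                ) else (np.full(nx, 1.0 / nx))
                for s in state_ids(spec_toks[1]):
                    P[a, s] = row
            else:
                for s in state_ids(spec_toks[1]):
                    for s2 in state_ids(spec_toks[2]):
                        P[a, s, s2] = rows[0][0]

    F = None
    if no:
        F = np.zeros((na, nx, no))
        for lineno, spec_toks, rows in o_blocks:
            for a in action_ids(spec_toks[0]):
                if len(spec_toks) == 1:
                    F[a] = expand_matrix(rows, (nx, no), lineno)
                elif len(spec_toks) == 2:
                    if rows[0] == "uniform":
                        row = np.full(no, 1.0 / no)
                    else:
                        row = expand_matrix(rows, (1, no), lineno)[0]
                    for s2 in state_ids(spec_toks[1]):
                        F[a, s2] = row
                else:
                    for s2 in state_ids(spec_toks[1]):
                        for o in obs_ids(spec_toks[2]):
                            F[a, s2, o] = rows[0][0]

    # R: a : s : s' : o  value  -> collapse to R(a|s) by averaging over s'
    # with the transition probabilities (observation wildcard required to be
    # constant over o; we take the per-(a,s,s') value).
    R_sas = np.zeros((na, nx, nx))
    for lineno, toks, val in r_entries:
        for a in action_ids(toks[0]):
            for s in state_ids(toks[1]):
                for s2 in state_ids(toks[2]):
                    R_sas[a, s, s2] = val
    R = (P * R_sas).sum(axis=-1)
    if header["values"] == "cost":
        R = -R

    try:
        return DecisionProcessSpec(
            state_labels=states,
            action_labels=actions,
            transitions=P,
            returns=R,
            discount=float(header["discount"]),
            horizon=INFINITE,
            observation_labels=observations if no else None,
            observations=F,
            name=path.stem,
        )
    except SpecValidationError as e:
        raise SpecValidationError(
            [f"{path}: {d}" for d in e.diagnostics]
        ) from e


def _dump_pomdp_text(spec: DecisionProcessSpec) -> str:
    out = [
        f"discount: {spec.discount!r}",
        "values: reward",
        "states: " + " ".join(spec.state_labels),
        "actions: " + " ".join(spec.action_labels),
    ]
    if spec.observation_labels:
        out.append("observations: " + " ".join(spec.observation_labels))
    for a, al in enumerate(spec.action_labels):
        out.append(f"T: {al}")
        for row in spec.transitions[a]:
            out.append(" ".join(repr(float(v)) for v in row))
    if spec.observations is not None:
        for a, al in enumerate(spec.action_labels):
            out.append(f"O: {al}")
            for row in spec.observations[a]:
                out.append(" ".join(repr(float(v)) for v in row))
    for a, al in enumerate(spec.action_labels):
        for s, sl in enumerate(spec.state_labels):
            out.append(f"R: {al} : {sl} : * : * {float(spec.returns[a, s])!r}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Auxiliary config blocks: adaptive-management models and density projection
# ---------------------------------------------------------------------------

def load_model_set(path):
    """Read the ``models:`` block of a structured config.

    Expected layout::

        models:
          labels: [y1, y2]
          transitions:            # one (|A|, |X|, |X|) array per model
            - [[[...]], ...]
            - [[[...]], ...]
          model_transition: [[...], ...]   # optional P(y'|y)
          returns:                         # optional per-model R(a|x)
            - [[...]]

    Returns an :class:`~ecopomdp.momdp_adaptive.ModelSet`.
    """
    from .momdp_adaptive import ModelSet

    path = Path(path)
    doc = yaml.safe_load(path.read_text()) if path.suffix != ".json" else json.loads(
        path.read_text()
    )
    if not isinstance(doc, dict) or "models" not in doc:
        raise ParseError(f"{path}: no 'models' block")
    block = doc["models"]
    for key in ("labels", "transitions"):
        if key not in block:
            raise ParseError(f"{path}: models block missing {key!r}")
    return ModelSet(
        model_labels=tuple(block["labels"]),
        transitions=np.asarray(block["transitions"], dtype=float),
        model_transition=(
            np.asarray(block["model_transition"], dtype=float)
            if "model_transition" in block
            else None
        ),
        returns=(
            np.asarray(block["returns"], dtype=float) if "returns" in block else None
        ),
    )


def load_projection_config(path):
    """Read the ``projection:`` block of a structured config.

    Expected keys: ``family`` (gaussian or beta), ``bounds`` (per-parameter
    [low, high]), ``counts`` (nodes per dimension), optional ``n_mc`` and
    ``seed``.  Returns a dict with the resolved ``family``,
    ``grid`` (:class:`~ecopomdp.density_projection.ParameterGrid`),
    ``n_mc`` and ``seed``.
    """
    from .density_projection import BETA, GAUSSIAN, ParameterGrid

    path = Path(path)
    doc = yaml.safe_load(path.read_text()) if path.suffix != ".json" else json.loads(
        path.read_text()
    )
    if not isinstance(doc, dict) or "projection" not in doc:
        raise ParseError(f"{path}: no 'projection' block")
    block = doc["projection"]
    families = {"gaussian": GAUSSIAN, "beta": BETA}
    if block.get("family") not in families:
        raise ParseError(
            f"{path}: projection family must be one of {sorted(families)}"
        )
    return {
        "family": families[block["family"]],
        "grid": ParameterGrid.regular(
            [tuple(b) for b in block["bounds"]], block["counts"]
        ),
        "n_mc": int(block.get("n_mc", 10_000)),
        "seed": int(block.get("seed", 0)),
    }
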