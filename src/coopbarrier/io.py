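"""File formats: DIMACS CNF, OR-Library-style set cover, JSON models/configs.

Gene and element indices are 1-based on disk (DIMACS convention) and
0-based in memory.  Clause weights, when not all 1, travel in DIMACS
comment lines ``c w <clause#> <weight>``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from coopbarrier.cooperation import CoverInstance, ILPInstance
from coopbarrier.landscapes import Clause, KSATInstance, MLPModel, SLPModel
from coopbarrier.viability import (
    KineticModel,
    StressSpec,
    linear_relaxation_model,
    michaelis_menten_chain,
)

__all__ = [
    "read_dimacs", "write_dimacs", "read_setcover", "write_setcover",
    "read_ilp_json", "write_ilp_json", "read_slp_json", "write_slp_json",
    "read_mlp_json", "write_mlp_json", "load_kinetic_config",
    "result_record", "dump_json",
]

SCHEMA_VERSION = 1


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# DIMACS CNF

def read_dimacs(path: str | Path) -> KSATInstance:
    """Read a K-SAT landscape from DIMACS CNF.

    Positive literal i means gene i must be expressed, negative literal
    means unexpressed.  ``c w k b`` comments set the weight of clause k.
    """
    n = m = None
    weights: dict[int, float] = {}
    tokens: list[tuple[int, int]] = []  # (literal, line number)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("c"):
                parts = line.split()
                if len(parts) == 4 and parts[1] == "w":
                    try:
                        weights[int(parts[2])] = float(parts[3])
                    except ValueError as exc:
                        raise ParseError(f"line {lineno}: bad weight comment") from exc
                continue
            if line.startswith("p"):
                parts = line.split()
                if len(parts) != 4 or parts[1] != "cnf":
                    raise ParseError(f"line {lineno}: malformed header {line!r}")
                try:
                    n, m = int(parts[2]), int(parts[3])
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: malformed header {line!r}") from exc
                continue
            if n is None:
                raise ParseError(f"line {lineno}: clause before 'p cnf' header")
            for tok in line.split():
                try:
                    lit = int(tok)
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: bad literal {tok!r}") from exc
                if lit != 0 and abs(lit) > n:
                    raise ParseError(
                        f"line {lineno}: literal {lit} outside 1..{n}"
                    )
                tokens.append((lit, lineno))
    if n is None:
        raise ParseError("missing 'p cnf' header")
    clauses: list[Clause] = []
    current: list[tuple[int, int]] = []
    for lit, lineno in tokens:
        if lit == 0:
            clauses.append(Clause(tuple(current)))
            current = []
        else:
            current.append((abs(lit) - 1, 1 if lit > 0 else -1))
    if current:
        raise ParseError("last clause not terminated by 0")
    if len(clauses) != m:
        raise ParseError(f"header declares {m} clauses, found {len(clauses)}")
    w = np.ones(len(clauses))
    for k, b in weights.items():
        if not 1 <= k <= len(clauses):
            raise ParseError(f"weight comment refers to clause {k} of {len(clauses)}")
        w[k - 1] = b
    return KSATInstance(n, clauses, w)


def write_dimacs(inst: KSATInstance, path: str | Path) -> None:
    lines = []
    if not np.allclose(inst.weights, 1.0):
        for k, b in enumerate(inst.weights, start=1):
            lines.append(f"c w {k} {b:g}")
    lines.append(f"p cnf {inst.n_genes} {inst.n_clauses}")
    for c in inst.clauses:
        lits = " ".join(str((i + 1) * pol) for i, pol in c.literals)
        lines.append(f"{lits} 0")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# set cover (OR-Library style)

def read_setcover(path: str | Path) -> CoverInstance:
    """Read ``M n`` header, n costs, then per element a count and the
    1-based indices of the subsets covering it.

    Duplicated indices are dropped with a warning; an element covered by
    no subset is kept (solvers will report infeasibility) with a warning.
    """
    toks: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            for tok in line.split():
                toks.append((tok, lineno))
    if len(toks) < 2:
        raise ParseError("missing 'M n' header")
    pos = 0

    def take(what: str) -> tuple[str, int]:
        nonlocal pos
        if pos >= len(toks):
            raise ParseError(f"unexpected end of file while reading {what}")
        t = toks[pos]
        pos += 1
        return t

    def take_int(what: str) -> int:
        tok, lineno = take(what)
        try:
            return int(tok)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad {what} {tok!r}") from exc

    m = take_int("universe size")
    n = take_int("family size")
    if n < 1:
        raise ParseError("empty subset family")
    if m < 1:
        raise ParseError("empty universe")
    costs = np.array([float(take("cost")[0]) for _ in range(n)])
    sets: list[set[int]] = [set() for _ in range(n)]
    for e in range(1, m + 1):
        count = take_int(f"covering-set count of element {e}")
        seen: set[int] = set()
        for _ in range(count):
            tok, lineno = take(f"covering set of element {e}")
            k = int(tok)
            if not 1 <= k <= n:
                raise ParseError(f"line {lineno}: set index {k} outside 1..{n}")
            if k in seen:
                warnings.warn(
                    f"element {e}: duplicated set index {k} dropped", stacklevel=2
                )
                continue
            seen.add(k)
            sets[k - 1].add(e)
        if count == 0:
            warnings.warn(f"element {e} is covered by no set", stacklevel=2)
    empty = [k + 1 for k, s in enumerate(sets) if not s]
    if empty:
        # CoverInstance forbids empty subsets; fail loudly with context
        raise ParseError(f"subsets {empty} cover no element")
    with warnings.catch_warnings():
        # the per-element warnings above already reported uncovered elements
        warnings.simplefilter("ignore")
        inst = CoverInstance(m, [frozenset(s) for s in sets], costs)
    return inst


def write_setcover(inst: CoverInstance, path: str | Path) -> None:
    lines = [f"{inst.universe_size} {inst.n_subsets}"]
    lines.append(" ".join(f"{c:g}" for c in inst.costs))
    covering: list[list[int]] = [[] for _ in range(inst.universe_size)]
    for k, s in enumerate(inst.family, start=1):
        for e in s:
            covering[e - 1].append(k)
    for row in covering:
        row.sort()
        lines.append(f"{len(row)} " + " ".join(map(str, row)) if row else "0")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# JSON: ILP instances, perceptron models, results

def write_ilp_json(inst: ILPInstance, path: str | Path) -> None:
    payload = {
        "schema": SCHEMA_VERSION,
        "a": inst.a.tolist(),
        "r": inst.r.tolist(),
        "h": inst.h.tolist(),
        "c_res": inst.c_res,
    }
    dump_json(payload, path)


def read_ilp_json(path: str | Path) -> ILPInstance:
    payload = json.loads(Path(path).read_text())
    return ILPInstance(
        a=np.asarray(payload["a"], dtype=float),
        r=np.asarray(payload["r"], dtype=float),
        h=np.asarray(payload["h"], dtype=float),
        c_res=payload.get("c_res"),
    )


def write_slp_json(model: SLPModel, path: str | Path) -> None:
    dump_json(
        {
            "schema": SCHEMA_VERSION,
            "kind": "slp",
            "W": model.W.tolist(),
            "h": model.h.tolist(),
            "r": model.r,
            "sigmoid": model.sigmoid,
        },
        path,
    )


def read_slp_json(path: str | Path) -> SLPModel:
    payload = json.loads(Path(path).read_text())
    return SLPModel(
        W=np.asarray(payload["W"], dtype=float),
        h=np.asarray(payload["h"], dtype=float),
        r=float(payload["r"]),
        sigmoid=payload["sigmoid"],
    )


def write_mlp_json(model: MLPModel, path: str | Path) -> None:
    dump_json(
        {
            "schema": SCHEMA_VERSION,
            "kind": "mlp",
            "layers": [
                {"W": W.tolist(), "h": h.tolist()} for W, h in model.layers
            ],
            "sigmoid": model.sigmoid,
        },
        path,
    )


def read_mlp_json(path: str | Path) -> MLPModel:
    payload = json.loads(Path(path).read_text())
    return MLPModel(
        layers=[
            (np.asarray(layer["W"], dtype=float), np.asarray(layer["h"], dtype=float))
            for layer in payload["layers"]
        ],
        sigmoid=payload["sigmoid"],
    )


# ---------------------------------------------------------------------------
# viability configs (YAML)

def load_kinetic_config(path: str | Path) -> dict[str, Any]:
    """Load a viability config: kinetic model + chain parameters.

    Recognized ``model.kind`` values: ``mm_chain`` (gated
    Michaelis-Menten chain) and ``linear`` (one-species relaxation).
    Returns a dict with keys ``model`` (KineticModel), ``genotype``
    (bit list or None) and ``chain`` (c0, gamma, innovation_rate, ...).
    """
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    out: dict[str, Any] = {"chain": cfg.get("chain", {}), "genotype": cfg.get("genotype")}
    model_cfg = cfg.get("model")
    if model_cfg is None:
        out["model"] = None
        return out
    kind = model_cfg.get("kind", "mm_chain")
    stress_cfg = model_cfg.get("stress")
    stress = (
        StressSpec(
            stress_cfg["name"],
            tuple(stress_cfg["params"]),
            int(stress_cfg.get("size", 1)),
        )
        if stress_cfg
        else None
    )
    if kind == "mm_chain":
        out["model"] = michaelis_menten_chain(
            n_stages=int(model_cfg.get("n_stages", 3)),
            vmax=float(model_cfg.get("vmax", 2.0)),
            km=float(model_cfg.get("km", 1.0)),
            decay=float(model_cfg.get("decay", 1.0)),
            stress=stress,
            thresholds=model_cfg.get("thresholds"),
        )
    elif kind == "linear":
        out["model"] = linear_relaxation_model(
            mu=float(model_cfg.get("mu", 2.0)),
            sigma=float(model_cfg.get("sigma", 1.0)),
            threshold=float(model_cfg.get("threshold", 1.0)),
        )
    else:
        raise ValueError(f"unknown kinetic model kind {kind!r}")
    return out


# ---------------------------------------------------------------------------
# result records

def _finite(obj):
    if isinstance(obj, dict):
        return {k: _finite(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_finite(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if not np.isfinite(v):
            raise ValueError("refusing to serialize a non-finite number")
        return v
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _finite(obj.tolist())
    return obj


def result_record(command: str, seed: int | None, **outputs) -> dict:
    """Uniform JSON result envelope: schema, provenance, outputs."""
    return _finite(
        {
            "schema": SCHEMA_VERSION,
            "command": command,
            "seed": seed,
            **outputs,
        }
    )


def dump_json(payload: dict, path: str | Path | None = None) -> str:
    text = json.dumps(_finite(payload), indent=2, allow_nan=False)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
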