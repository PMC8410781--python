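"""Reproducible orchestration: configs, the full analysis pipeline, fixtures.

``run_pipeline`` ties the stages together the way a typical analysis runs:
find the attractors of a network (exhaustively, modularly, or by sampling),
compute a control kernel for every attractor, the iterative bounds, the
first-order approximation, the input entropy, and a per-network summary,
and serialize everything deterministically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .attractors import (AttractorSet, find_attractors_exhaustive,
                         find_attractors_sampled)
from .kernel import (find_control_kernel, iterative_bound, network_summary)
from .modular import find_attractors_modular
from .network import BooleanNetwork, parse_network

__all__ = ["RunConfig", "run_pipeline", "generate_fixtures", "FIXTURES"]

log = logging.getLogger("boolck")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``method`` selects the attractor search: ``exhaustive`` (exact basins),
    ``modular`` (exact attractors, no basins) or ``sample`` (requires
    ``n_samples`` and ``seed``).  Budgets cap pinned-dynamics evaluations,
    iterative rounds and the exhaustive state-space size.
    """

    network_path: str | None = None
    network_text: str | None = None
    dialect: str = "bnet"
    method: str = "exhaustive"
    n_samples: int | None = None
    seed: int | None = None
    pin_budget: int = 1_000_000
    round_cap: int = 50
    state_cap: int = 22
    compute_bounds: bool = True
    out_json: str | None = None
    out_csv: str | None = None

    def validate(self):
        if self.method not in ("exhaustive", "modular", "sample"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "sample" and (self.n_samples is None
                                        or self.seed is None):
            raise ValueError("sample method requires n_samples and seed")
        if self.pin_budget <= 0 or self.round_cap <= 0 or self.state_cap <= 0:
            raise ValueError("budgets must be positive")
        if (self.network_path is None) == (self.network_text is None):
            raise ValueError("provide exactly one of network_path/network_text")


def _load_network(config: RunConfig) -> BooleanNetwork:
    text = config.network_text
    if text is None:
        text = Path(config.network_path).read_text()
    dialect = config.dialect
    if dialect == "auto":
        dialect = ("json-truthtable"
                   if text.lstrip().startswith("{") else "bnet")
    return parse_network(text, dialect=dialect)


def _find_attractors(net: BooleanNetwork, config: RunConfig) -> AttractorSet:
    if config.method == "exhaustive":
        return find_attractors_exhaustive(net, cap=config.state_cap)
    if config.method == "modular":
        return find_attractors_modular(net, cap=1 << config.state_cap)
    return find_attractors_sampled(net, config.n_samples, config.seed)


def run_pipeline(config: RunConfig) -> dict:
    """Run attractor finding, CK search and bounds; return the result bundle.

    Deterministic given the config (and seed, in sampled mode).  Writes JSON
    results and a CSV summary when output paths are configured.  The bundle's
    ``outcome`` is ``success`` if every attractor got an exact CK,
    ``bound_only`` if budgets were hit, ``uncontrollable_only`` if no
    attractor is statically controllable.
    """
    config.validate()
    net = _load_network(config)
    aset = _find_attractors(net, config)
    ck_results = []
    budget_hit = False
    for a in aset.attractors:
        res = find_control_kernel(net, a, aset, budget=config.pin_budget)
        if res.status == "bound_only":
            budget_hit = True
            log.warning("pin-test budget hit for attractor %s", a.states)
        record = dataclasses.asdict(res)
        if config.compute_bounds and res.status == "exact":
            lo, up, rounds, st = iterative_bound(net, a, aset,
                                                 round_cap=config.round_cap)
            record["lower"], record["upper"] = lo, up
            record["rounds"] = [
                {"pinned": list(nm), "size": sz, "attractors_remaining": rem}
                for nm, sz, rem in rounds]
            if st == "bound_only":
                budget_hit = True
                log.warning("round cap hit for attractor %s", a.states)
        ck_results.append((res, record))
    summary = network_summary(net, aset, [r for r, _ in ck_results],
                              budget=config.pin_budget)
    n_exact = sum(1 for r, _ in ck_results if r.status == "exact")
    if n_exact == len(ck_results):
        outcome = "success"
    elif n_exact == 0 and summary["n_uncontrollable"] == len(ck_results):
        outcome = "uncontrollable_only"
    elif budget_hit or summary["n_bound_only"]:
        outcome = "bound_only"
    else:
        outcome = "success"
    bundle = {
        "version": __version__,
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if k != "network_text"},
        "attractors": aset.to_json_obj(),
        "control_kernels": [rec for _, rec in ck_results],
        "summary": summary,
        "outcome": outcome,
    }
    if config.out_json:
        Path(config.out_json).write_text(_to_json(bundle))
    if config.out_csv:
        import pandas as pd
        rows = []
        for _, rec in ck_results:
            rows.append({
                "target": "|".join(str(s) for s in rec["target"]),
                "status": rec["status"],
                "ck": ";".join(rec["ck"] or ()) if rec["ck"] is not None else "",
                "size": rec["size"], "m": rec["m"],
                "w1": rec["w1_size"], "additional": rec["additional"],
                "lower": rec["lower"], "upper": rec["upper"],
            })
        pd.DataFrame(rows).to_csv(config.out_csv, index=False)
    return bundle


def _round_floats(obj, sig=12):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def _to_json(bundle: dict) -> str:
    return json.dumps(_round_floats(bundle), indent=1, sort_keys=True,
                      default=str)


# ---------------------------------------------------------------------------
# canonical fixtures

#: Small hand-checkable networks covering fixed points, cycles, modules,
#: uncontrollable cycles, and a controllable (gated) cycle.
FIXTURES: dict[str, str] = {
    # one input node driving a chain: m=1, r=2 fixed points
    "input_chain": "A, A\nB, A\nC, B\n",
    # mutual negation: 2 fixed points + one uncontrollable 2-cycle
    "toggle": "A, !B\nB, !A\n",
    # single-node negation: one 2-cycle filling the space
    "negation_cycle": "A, !A\n",
    # two independent toggles: 3 x 3 = 9 product attractors
    "double_toggle": "A, !B\nB, !A\nC, !D\nD, !C\n",
    # input gate G turns a 2-node oscillator on (cycle) or off (fixed point);
    # the cycle's only constant node is G, and pinning G=1 isolates it
    "gated_oscillator": "G, G\nX, G & !Y\nY, G & X\n",
    # disjoint pure rotation rings of lengths 2 and 3 (cycle composition)
    "rings_2_3": ("P0, P1\nP1, P0\n"
                  "Q0, Q2\nQ1, Q0\nQ2, Q1\n"),
}


def generate_fixtures(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write the canonical fixtures and exhaustive-oracle sidecar files.

    Each fixture ``name.bnet`` gets a ``name.expected.json`` produced by the
    exhaustive attractor finder (r, attractor lengths, basin sizes, input
    count), so expectations regenerate identically from the oracle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, text in FIXTURES.items():
        net = parse_network(text)
        aset = find_attractors_exhaustive(net)
        from .network import input_nodes
        sidecar = {
            "r": aset.r,
            "m": len(input_nodes(net)),
            "lengths": sorted(a.length for a in aset.attractors),
            "basin_sizes": sorted(a.basin_size for a in aset.attractors),
            "seed": seed,
            "version": __version__,
        }
        p1 = out / f"{name}.bnet"
        p1.write_text(text)
        p2 = out / f"{name}.expected.json"
        p2.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        written += [p1, p2]
    return written
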