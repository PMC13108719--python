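"""Shared fixtures: toy reference sets and an end-to-end pipeline runner."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest

from splitpea.fixtures import (ToyConfig, ToyReferences, PlannedEvent,
                               make_toy_references, make_toy_rmats,
                               make_toy_suppa, make_truth_plan)
from splitpea.reference_data import (DDICatalog, DomainIndex, IdMap, PPINetwork,
                                     load_ddi, load_domain_coords, load_id_map,
                                     load_ppi)
from splitpea.rewire import RewiredNetwork, build_rewired_network
from splitpea.splice_io import filter_significant, parse_rmats, parse_suppa


@dataclass
class ToyRun:
    cfg: ToyConfig
    toy: ToyReferences
    plan: list[PlannedEvent]
    idmap: IdMap
    ppi: PPINetwork
    ddi: DDICatalog
    index: DomainIndex
    net: RewiredNetwork
    outdir: Path


def run_toy_pipeline(cfg: ToyConfig, outdir: Path, fmt: str = "rmats",
                     **build_kwargs) -> ToyRun:
    """Generate toy files for ``cfg``, load them through the real loaders and
    build the rewired network via the parse -> filter -> rewire path."""
    toy = make_toy_references(cfg, outdir)
    plan = make_truth_plan(cfg, toy)
    idmap = load_id_map(outdir / "idmap.tsv")
    ppi = load_ppi(outdir / "ppi.tsv", idmap)
    ddi = load_ddi(outdir / "ddi.tsv")
    index = load_domain_coords(outdir / "domains.tsv", idmap)
    if fmt == "rmats":
        events = parse_rmats(make_toy_rmats(cfg, plan, toy, outdir / "toy.rmats.txt"), idmap)
    else:
        dpsi, psivec = make_toy_suppa(cfg, plan, toy, outdir)
        events = parse_suppa(dpsi, psivec, idmap)
    net = build_rewired_network(filter_significant(events), ppi, ddi, index,
                                **build_kwargs)
    return ToyRun(cfg, toy, plan, idmap, ppi, ddi, index, net, outdir)


def varied_config(seed: int) -> ToyConfig:
    """A deterministic family of toy configurations spanning network shapes."""
    return ToyConfig(
        seed=seed,
        n_genes=5 + (seed * 7) % 21,
        n_pfam=4 + seed % 7,
        ppi_density=0.2 + 0.6 * ((seed * 3) % 5) / 5,
        ddi_density=0.2 + 0.6 * ((seed * 5) % 5) / 5,
        n_events=10 + (seed * 11) % 25,
        n_self_ppi=seed % 3,
        frac_significant=0.6 + 0.3 * (seed % 4) / 4,
    )


@pytest.fixture
def toy_run(tmp_path) -> ToyRun:
    return run_toy_pipeline(ToyConfig(seed=3), tmp_path)
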