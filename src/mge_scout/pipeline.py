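"""Full-scan orchestration: stats, repeats, topology, ESX, classification."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .classify import build_profile, delimit_integrated_regions
from .esx import call_esx_loci, type_esx_loci
from .records import (
    AnnotatedReplicon,
    ElementProfile,
    EsxLocus,
    IntegratedRegionCall,
    ReadPairLink,
    TopologyCall,
)
from .repeats import find_repeats
from .topology import TopologyParams, call_topology

logger = logging.getLogger(__name__)


@dataclass
class ScanParams:
    """Tunables for the full pipeline, overridable from the YAML config."""

    topology: TopologyParams = field(default_factory=TopologyParams)
    dr_min_len: int = 100          # genome-wide direct-repeat scan floor
    # integration-boundary DRs are typically perfect copies; an exact scan
    # keeps their reported extent exact (lower for degraded boundaries)
    dr_min_identity: float = 100.0
    esx_max_gap: int = 6000
    esx_min_core: int = 4
    esx_ecca_reach: int = 20000
    region_max_adjacency: int = 1000

    @classmethod
    def from_config(cls, cfg: dict) -> "ScanParams":
        params = cls()
        topo_cfg = cfg.get("topology", {})
        for key, val in topo_cfg.items():
            if not hasattr(params.topology, key):
                raise ValueError(f"unknown topology option {key!r}")
            setattr(params.topology, key, val)
        for key, val in cfg.items():
            if key == "topology":
                continue
            if not hasattr(params, key):
                raise ValueError(f"unknown option {key!r}")
            setattr(params, key, val)
        return params


@dataclass
class ScanResult:
    profiles: list[ElementProfile]
    topology_calls: list[TopologyCall]
    esx_loci: list[EsxLocus]
    regions: list[IntegratedRegionCall]


def scan_replicons(
    replicons: Sequence[AnnotatedReplicon],
    links: Optional[Sequence[ReadPairLink]] = None,
    params: Optional[ScanParams] = None,
) -> ScanResult:
    """Run every stage on each replicon and assemble the element report."""
    p = params or ScanParams()
    profiles, topo_calls, all_loci, all_regions = [], [], [], []
    for rep in replicons:
        logger.info("scanning %s (%d bp, %d features)", rep.id, len(rep),
                    len(rep.features))
        topo = call_topology(rep, links, p.topology)
        loci = type_esx_loci(
            call_esx_loci(rep, p.esx_max_gap, p.esx_min_core, p.esx_ecca_reach)
        )
        drs = find_repeats(
            rep.sequence, "direct", p.dr_min_len, p.dr_min_identity
        )
        regions = delimit_integrated_regions(rep, drs, p.region_max_adjacency)
        profiles.append(build_profile(rep, topo, loci))
        topo_calls.append(topo)
        all_loci.extend(loci)
        all_regions.extend(regions)
    return ScanResult(profiles, topo_calls, all_loci, all_regions)
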