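"""End-to-end convenience wrapper: localization table -> interblade distances."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .locfilter import FilterConfig, run_filter_pipeline
from .trimer_geometry import ClusterConfig, TrimerRules, cluster_protomers, find_trimers


@dataclass
class MinfluxPipelineResult:
    centers: pd.DataFrame
    sites: pd.DataFrame
    trimers: pd.DataFrame
    report: dict

    @property
    def interblade_distances(self) -> np.ndarray:
        """Interblade distances (nm) of all accepted trimers."""
        return self.trimers["interblade_nm"].to_numpy(float)


def run_minflux_pipeline(
    table: pd.DataFrame,
    filter_config: FilterConfig | None = None,
    cluster_config: ClusterConfig | None = None,
    rules: TrimerRules | None = None,
) -> MinfluxPipelineResult:
    """Filter localizations, merge traces into protomer sites, find trimers."""
    filt = run_filter_pipeline(table, filter_config)
    sites = cluster_protomers(filt.centers, cluster_config)
    trimers = find_trimers(sites, rules)
    report = dict(filt.report)
    report["n_sites"] = int(len(sites))
    report["n_trimers"] = int(len(trimers))
    return MinfluxPipelineResult(
        centers=filt.centers, sites=sites, trimers=trimers, report=report
    )
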