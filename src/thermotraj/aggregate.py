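"""Replica pooling, boxplot-style summary statistics, percent-change
arithmetic and the end-to-end report pipeline."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import descriptors, interactions, secondary_structure
from .descriptors import DescriptorSeries
from .io_structures import ReplicaSet, read_pdb

__all__ = [
    "SummaryStats",
    "TemperatureComparison",
    "PooledSeries",
    "pool_replicas",
    "summarize",
    "percent_excess",
    "percent_decrease",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

SKEW_BAND = 1e-9


@dataclasses.dataclass
class SummaryStats:
    """Tukey boxplot summary of a pooled sample."""

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    n_outliers: int
    skew_direction: str  # left | right | symmetric

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class TemperatureComparison:
    protein: str
    descriptor: str
    kind: str  # "temperature" or "protein"
    reference: str
    other: str
    reference_mean: float
    other_mean: float
    difference: float
    percent: float


@dataclasses.dataclass
class PooledSeries:
    """Concatenated per-replica values with provenance tags."""

    name: str
    values: np.ndarray
    replica_of: np.ndarray  # same length, replica index per value

    @property
    def n(self) -> int:
        return len(self.values)


def pool_replicas(series_list: Sequence[DescriptorSeries]) -> PooledSeries:
    """Concatenate per-replica descriptor series, keeping provenance.

    All series must carry the same descriptor name (e.g. three replicas
    of 10,001 frames pool to n = 30,003).
    """
    if not series_list:
        raise ValueError("at least one series required")
    name = series_list[0].name
    for s in series_list[1:]:
        if s.name != name:
            raise ValueError(
                f"cannot pool different descriptors: {name!r} vs {s.name!r}"
            )
    values = np.concatenate([s.values for s in series_list])
    replica_of = np.concatenate(
        [np.full(len(s), i, dtype=np.intp) for i, s in enumerate(series_list)]
    )
    return PooledSeries(name=name, values=values, replica_of=replica_of)


def summarize(values: np.ndarray | Sequence[float] | PooledSeries) -> SummaryStats:
    """Tukey-convention summary: linear-interpolation quartiles, whiskers
    at the most extreme datum within 1.5*IQR of the quartiles, outliers
    beyond the whiskers, skew by the mean-vs-median sign."""
    if isinstance(values, PooledSeries):
        values = values.values
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    q1, median, q3 = (float(v) for v in np.percentile(x, [25, 50, 75]))
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())
    n_outliers = int(np.sum((x < whisker_low) | (x > whisker_high)))
    if abs(mean - median) <= SKEW_BAND:
        skew = "symmetric"
    elif mean < median:
        skew = "left"
    else:
        skew = "right"
    return SummaryStats(
        n=int(x.size),
        mean=mean,
        sd=sd,
        median=median,
        q1=q1,
        q3=q3,
        iqr=iqr,
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        n_outliers=n_outliers,
        skew_direction=skew,
    )


def percent_excess(reference_mean: float, other_mean: float) -> float:
    """Signed percent by which ``other_mean`` exceeds ``reference_mean``:
    100 * (other - reference) / reference."""
    if reference_mean == 0:
        raise ZeroDivisionError("reference mean must be non-zero")
    return 100.0 * (other_mean - reference_mean) / reference_mean


def percent_decrease(initial_mean: float, final_mean: float) -> float:
    """Percent decrease from an initial to a final mean:
    100 * (initial - final) / initial."""
    if initial_mean == 0:
        raise ZeroDivisionError("initial mean must be non-zero")
    return 100.0 * (initial_mean - final_mean) / initial_mean


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _write_csv(path: Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False, float_format="%.6f")


def run_pipeline(config, output_dir: str | Path | None = None) -> dict:
    """Run the full per-protein, per-temperature analysis.

    ``config`` is a mapping (or YAML path) of the form::

        output_dir: out
        rmsd_selection: ca           # optional
        hbond: {r_max: 3.5, theta_max: 30.0}
        saltbridge: {r_max: 4.0, threshold: 0.30}
        reference_temperature: 302
        proteins:
          - name: ProtA
            temperatures:
              - temperature: 302
                replicas: [path1.pdb, path2.pdb, path3.pdb]

    Emits per protein and temperature: descriptor CSVs, pooled summary
    tables, SS content tables, hydrogen-bond counts, salt-bridge
    frequency tables and network JSON, plus a cross-temperature /
    cross-protein comparison table and a run log of every threshold.
    Returns the report bundle as nested dictionaries.
    """
    cfg = _load_config(config)
    out_dir = Path(output_dir or cfg.get("output_dir", "report_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    rmsd_sel = cfg.get("rmsd_selection", "ca")
    hb_cfg = cfg.get("hbond", {})
    criteria = interactions.HBondCriteria(
        r_max=float(hb_cfg.get("r_max", 3.5)),
        theta_max=float(hb_cfg.get("theta_max", 30.0)),
    )
    sb_cfg = cfg.get("saltbridge", {})
    sb_rmax = float(sb_cfg.get("r_max", 4.0))
    sb_threshold = float(sb_cfg.get("threshold", 0.30))
    ref_temp = cfg.get("reference_temperature")

    run_log = {
        "rmsd_selection": rmsd_sel,
        "hbond_r_max_A": criteria.r_max,
        "hbond_theta_max_deg": criteria.theta_max,
        "hbond_angle_convention": "at-donor (D->H vs D->A)",
        "saltbridge_r_max_A": sb_rmax,
        "saltbridge_formation_threshold": sb_threshold,
        "stability_class_boundaries": [0.75, 0.50, 0.30],
        "native_contact_params": {"beta_invA": 5.0, "lambda": 1.8,
                                  "cutoff_A": 4.5, "min_seq_sep": 3},
    }

    bundle: dict = {"run_log": run_log, "proteins": {}}
    pooled_means: dict[tuple[str, str, float], float] = {}

    for prot in cfg["proteins"]:
        pname = prot["name"]
        bundle["proteins"][pname] = {}
        for entry in prot["temperatures"]:
            temp = float(entry["temperature"])
            paths = entry["replicas"]
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"replica trajectory not found: {p}")
            replicas = [read_pdb(p) for p in paths]
            rset = ReplicaSet(temperature=temp, replicas=replicas, label=pname)
            tag = f"{pname}_{int(temp)}K"
            logger.info("analyzing %s (%d replicas)", tag, len(replicas))

            per_desc: dict[str, list[DescriptorSeries]] = {"RMSD": [], "Rg": [], "Q": []}
            hbond_rows = []
            for ri, traj in enumerate(replicas):
                per_desc["RMSD"].append(descriptors.rmsd_series(traj, rmsd_sel))
                per_desc["Rg"].append(descriptors.radius_of_gyration_series(traj))
                contacts = descriptors.native_contacts(traj)
                per_desc["Q"].append(descriptors.q_series(traj, contacts))
                hb = interactions.hbond_series(traj, "pp", criteria)
                for t, c in zip(hb.times, hb.counts):
                    hbond_rows.append({"replica": ri, "time_ps": t, "hb_pp": c})

            summaries = {}
            for dname, series in per_desc.items():
                pooled = pool_replicas(series)
                stats = summarize(pooled)
                summaries[dname] = stats
                pooled_means[(pname, dname, temp)] = stats.mean
                rows = []
                for ri, s in enumerate(series):
                    for t, v in zip(s.times, s.values):
                        rows.append({"replica": ri, "time_ps": t, "value": v})
                _write_csv(out_dir / f"{tag}_{dname.lower()}.csv", pd.DataFrame(rows))
            _write_csv(out_dir / f"{tag}_hbpp.csv", pd.DataFrame(hbond_rows))

            ss_rows = []
            for ri, traj in enumerate(replicas):
                content = secondary_structure.ss_content_series(traj)
                for k in range(len(content.times)):
                    ss_rows.append(
                        {
                            "replica": ri,
                            "time_ps": content.times[k],
                            "alpha": content.alpha[k],
                            "beta": content.beta[k],
                            "coil": content.coil[k],
                        }
                    )
            _write_csv(out_dir / f"{tag}_ss_content.csv", pd.DataFrame(ss_rows))

            obs = interactions.salt_bridge_frequencies(rset, r_max=sb_rmax)
            formed = interactions.formed_pairs(obs, threshold=sb_threshold)
            sb_rows = [
                {
                    "basic": str(o.basic_residue),
                    "acidic": str(o.acidic_residue),
                    "f_mean": o.f_mean,
                    **{f"f_rep{ri + 1}": f for ri, f in enumerate(o.f_per_replica)},
                    "stability": o.stability.value,
                }
                for o in sorted(obs, key=lambda o: -o.f_mean)
            ]
            _write_csv(out_dir / f"{tag}_saltbridges.csv", pd.DataFrame(sb_rows))
            networks = interactions.build_networks(formed)
            net_json = [
                {
                    "motif": n.motif,
                    "members": sorted(str(m) for m in n.members),
                    "edges": [[str(u), str(v)] for u, v in n.edges],
                }
                for n in networks
            ]
            (out_dir / f"{tag}_networks.json").write_text(
                json.dumps(net_json, indent=1, sort_keys=True) + "\n"
            )

            bundle["proteins"][pname][temp] = {
                "summaries": {k: v.as_dict() for k, v in summaries.items()},
                "n_formed_saltbridges": len(formed),
                "networks": net_json,
                "observations": obs,
            }

    comparisons: list[TemperatureComparison] = []
    if ref_temp is not None:
        ref_temp = float(ref_temp)
        for (pname, dname, temp), mean in sorted(pooled_means.items()):
            ref_mean = pooled_means.get((pname, dname, ref_temp))
            if ref_mean is None or temp == ref_temp or ref_mean == 0:
                continue
            comparisons.append(
                TemperatureComparison(
                    protein=pname,
                    descriptor=dname,
                    kind="temperature",
                    reference=f"{ref_temp:g}K",
                    other=f"{temp:g}K",
                    reference_mean=ref_mean,
                    other_mean=mean,
                    difference=mean - ref_mean,
                    percent=percent_excess(ref_mean, mean),
                )
            )
    prot_names = [p["name"] for p in cfg["proteins"]]
    if len(prot_names) >= 2:
        ref_p = prot_names[0]
        for other_p in prot_names[1:]:
            for (pname, dname, temp), mean in sorted(pooled_means.items()):
                if pname != ref_p:
                    continue
                other_mean = pooled_means.get((other_p, dname, temp))
                if other_mean is None or mean == 0:
                    continue
                comparisons.append(
                    TemperatureComparison(
                        protein=f"{ref_p}->{other_p}",
                        descriptor=dname,
                        kind="protein",
                        reference=ref_p,
                        other=other_p,
                        reference_mean=mean,
                        other_mean=other_mean,
                        difference=other_mean - mean,
                        percent=percent_excess(mean, other_mean),
                    )
                )
    _write_csv(
        out_dir / "comparisons.csv",
        pd.DataFrame([dataclasses.asdict(c) for c in comparisons]),
    )
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=1) + "\n")
    bundle["comparisons"] = comparisons
    return bundle
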