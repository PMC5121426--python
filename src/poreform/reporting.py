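"""Assemble analysis results into tables, figures and a manifest.

Figures are conveniences; the numeric artifacts (TSV/JSON) are the record
and are byte-reproducible under a fixed configuration and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

MANIFEST_SCHEMA_VERSION = 1


class AnalysisBundle:
    """Any subset of per-trajectory results, with provenance metadata
    (input paths, config hash, seed, toolkit version)."""

    def __init__(self, population=None, clusters=None, two_state=None,
                 density=None, conduction=None, arrhenius=None, provenance=None):
        self.population = population
        self.clusters = clusters          # order -> ClusterResult
        self.two_state = two_state
        self.density = density
        self.conduction = conduction
        self.arrhenius = arrhenius
        self.provenance = provenance or {}

    def is_empty(self) -> bool:
        return all(
            x is None
            for x in (self.population, self.clusters, self.two_state,
                      self.density, self.conduction, self.arrhenius)
        )


def _fig(path: Path, draw) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    draw(ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(bundle: AnalysisBundle, out_dir: str | Path) -> dict:
    """Write every available result as TSV/JSON (+ figure) and a manifest."""
    if bundle.is_empty():
        raise ValueError("nothing to report: the bundle is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[dict] = []

    def record(name: str, kind: str, params: dict | None = None) -> Path:
        artifacts.append({"file": name, "kind": kind, "params": params or {}})
        return out / name

    if bundle.population is not None:
        pop = bundle.population
        path = record("population_occupancy.tsv", "table",
                      {"n_peptides": pop.n_peptides})
        pop.occupancy.to_csv(path, sep="\t", float_format="%.6f")
        summary = {
            "mean_occupancy": {int(k): float(v) for k, v in pop.mean.items()},
            "sem_occupancy": {
                int(k): (None if np.isnan(v) else float(v))
                for k, v in pop.sem.items()
            },
        }
        record("population_summary.json", "summary").write_text(
            json.dumps(summary, indent=1, sort_keys=True)
        )
        _fig(record("population_occupancy.png", "figure"), lambda ax: (
            ax.stackplot(
                pop.occupancy.index,
                [pop.occupancy[c] for c in pop.occupancy.columns],
                labels=[f"n={c}" for c in pop.occupancy.columns],
            ),
            ax.set_xlabel("time (ps)"), ax.set_ylabel("peptide mass fraction"),
            ax.legend(fontsize=7, ncol=2),
        ))

    if bundle.clusters is not None:
        manifest = []
        for order in sorted(bundle.clusters):
            res = bundle.clusters[order]
            for ci, cl in enumerate(res.clusters):
                manifest.append({
                    "order": int(order),
                    "cluster": ci,
                    "population": round(cl.population, 6),
                    "scheme": cl.scheme,
                    "class": cl.topology_class,
                    "founder_frame": int(res.observations[cl.founder].frame_index),
                    "n_members": len(cl.members),
                })
        record("clusters.json", "summary", {"cutoff": 4.0}).write_text(
            json.dumps(manifest, indent=1)
        )

    if bundle.two_state is not None:
        ts = bundle.two_state
        record("two_state.json", "summary").write_text(json.dumps({
            "p_surface": ts.p_surface,
            "p_tm": ts.p_tm,
            "temperature_K": ts.temperature,
            "dG_S_to_TM_kcal_mol": round(ts.dg_s_to_tm, 4),
            "sem_p_surface": None if np.isnan(ts.sem_p_surface) else ts.sem_p_surface,
        }, indent=1))

    if bundle.density is not None:
        dm = bundle.density
        path = record("density_map.tsv", "table",
                      {"smooth_window": dm.smooth_window})
        header = "\t".join(f"{t:.1f}" for t in dm.times)
        rows = [
            f"{0.5 * (dm.z_edges[i] + dm.z_edges[i + 1]):.2f}\t"
            + "\t".join(f"{v:.6f}" for v in dm.values[i])
            for i in range(dm.values.shape[0])
        ]
        path.write_text("z_A\\time_ps\t" + header + "\n" + "\n".join(rows) + "\n")
        _fig(record("density_map.png", "figure"), lambda ax: (
            ax.imshow(dm.values, aspect="auto", origin="lower",
                      extent=[dm.times[0], dm.times[-1],
                              dm.z_edges[0], dm.z_edges[-1]]),
            ax.set_xlabel("time (ps)"), ax.set_ylabel("z (Å)"),
        ))

    if bundle.conduction is not None:
        cs = bundle.conduction
        record("conduction.json", "summary",
               {"voltage_mv": cs.voltage_mv}).write_text(json.dumps({
                   "counts": cs.counts,
                   "rates_per_us": cs.rates,
                   "direction_split": {k: list(v) for k, v in cs.direction_split.items()},
                   "selectivity": cs.selectivity,
                   "duration_us": cs.duration_us,
                   "water_volume_flux_A3_per_us": cs.water_volume_flux,
               }, indent=1, sort_keys=True))

    if bundle.arrhenius is not None:
        fit = bundle.arrhenius
        record("arrhenius.json", "summary").write_text(json.dumps({
            "Ea_kcal_mol": fit.ea,
            "ln_A_ps": fit.ln_a,
            "covariance": fit.covariance.tolist(),
            "temperatures_K": fit.temperatures.tolist(),
            "mean_tau_ps": fit.mean_tau.tolist(),
            "n_censored": fit.n_censored,
        }, indent=1))
        _fig(record("arrhenius.png", "figure"), lambda ax: (
            ax.plot(1.0 / fit.temperatures, np.log(fit.mean_tau), "o"),
            ax.set_xlabel("1/T (1/K)"), ax.set_ylabel("ln tau (ps)"),
        ))

    manifest = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "provenance": bundle.provenance,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
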