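"""End-to-end pipeline driver.

Runs the enabled stages in workflow order on synthetic (or supplied) data:

    generate/load -> clean -> VIF selection -> fit -> applicability domain
    -> ALE -> ensemble / refinement -> contacts

plus a docking-validation stage on the packaged reference-ligand tables.
Each stage writes its outputs under ``output_dir``, stamped with a hash of
the configuration, and the run ends with a ``manifest.json`` recording
seeds, policy settings, and per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .affinity import validate_against_experiment
from .ale import ale_summary
from .contacts import aggregate_frequencies, export_fasta, find_contacts
from .descriptors import clean, iterative_vif_elimination
from .domain import applicability_domain
from .fixtures import load_fixture
from .io import write_json, write_table
from .qspr import cross_validate_q2, fit_ols
from .synthetic import generate_complex, generate_dataset, pfas_like_spec
from .validation import enumerate_pair_splits, iterative_outlier_refinement, run_ensemble

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Raised with the failing stage's name; earlier outputs are retained."""


@dataclass
class PipelineConfig:
    """Stage toggles and the knobs of every stage, with recorded seeds."""

    output_dir: str = "pfaser-run"
    seed: int = 0
    # stage toggles
    validate_docking: bool = True
    simulate: bool = True
    run_clean: bool = True
    run_vif: bool = True
    run_fit: bool = True
    run_ad: bool = True
    run_ale: bool = True
    run_ensemble: bool = False
    run_refinement: bool = False
    run_contacts: bool = False
    # stage parameters
    n_ligands: int = 69
    noise_sd: float = 0.35
    temperature_K: float = 300.0
    vif_threshold: float = 5.0
    residual_limit: float = 3.0
    ale_grid_size: int = 20
    n_experimental: int = 12
    n_pool_test: int = 5
    n_pool_train: int = 45
    refinement_fractions: tuple = (0.10, 0.20)
    score_cutoff: float = -7.0
    n_complexes: int = 5
    n_residues: int = 20
    contact_cutoff: float = 5.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if "refinement_fractions" in d:
            d["refinement_fractions"] = tuple(d["refinement_fractions"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific settings (the output path is excluded, so
        identical analyses hash identically wherever they are written)."""
        d = asdict(self)
        d.pop("output_dir")
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the manifest dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"config_hash: {config.config_hash}"
    manifest: dict = {
        "pfaser_version": __version__,
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash,
        "stages": {},
    }
    stage = "init"
    try:
        if config.validate_docking:
            stage = "validate_docking"
            results = {}
            for receptor, fixture in (
                ("ERalpha", "table1_era_ligands"),
                ("ERbeta", "table2_erb_ligands"),
            ):
                tab = load_fixture(fixture)
                summary = validate_against_experiment(
                    list(zip(tab["ic50_nM"], tab["autodock_ic50_nM"]))
                )
                results[receptor] = {
                    "n": summary.n,
                    "mean_difference": summary.mean_difference,
                    "sd": summary.sd,
                    "standard_error": summary.standard_error,
                }
            write_json({"config_hash": config.config_hash, **results},
                       out / "docking_validation.json")
            manifest["stages"]["validate_docking"] = results

        dataset = None
        if config.simulate:
            stage = "simulate"
            spec = pfas_like_spec(
                n_ligands=config.n_ligands,
                noise_sd=config.noise_sd,
                seed=config.seed,
            )
            dataset = generate_dataset(spec)
            write_table(dataset.descriptor_table, out / "descriptors.csv", stamp)
            affin = pd.DataFrame(
                {
                    "pic50": dataset.observed_pic50,
                    "true_pic50": dataset.true_pic50,
                    "score_kcal_mol": dataset.docking_scores,
                }
            )
            write_table(affin, out / "affinities.csv", stamp)
            manifest["stages"]["simulate"] = {
                "n_ligands": config.n_ligands,
                "seed": config.seed,
                "noise_sd": config.noise_sd,
            }

        table = dataset.descriptor_table if dataset is not None else None
        y = dataset.observed_pic50 if dataset is not None else None
        if table is None and any(
            [config.run_clean, config.run_fit, config.run_vif, config.run_ad]
        ):
            raise PipelineError("downstream stages need simulate=True or inputs")

        if config.run_clean and table is not None:
            stage = "clean"
            result = clean(table)
            manifest["stages"]["clean"] = {
                "n_in": len(table),
                "n_removed": result.n_removed,
                "n_out": len(result.table),
            }
            table = result.table
            y = y.loc[table.index]

        if config.run_vif and table is not None:
            stage = "vif"
            table, report = iterative_vif_elimination(
                table, threshold=config.vif_threshold
            )
            write_table(report.vif.to_frame(), out / "vif.csv", stamp)
            manifest["stages"]["vif"] = {
                "threshold": config.vif_threshold,
                "removed": [name for name, _ in report.removal_history],
                "n_descriptors_out": table.shape[1],
            }

        model = None
        if config.run_fit and table is not None:
            stage = "fit"
            model = fit_ols(table, y)
            model.metrics.q2 = cross_validate_q2(table, y)
            (out / "model.json").write_text(model.to_json(indent=2) + "\n")
            manifest["stages"]["fit"] = {
                "r2": model.metrics.r2,
                "rmse": model.metrics.rmse,
                "mae": model.metrics.mae,
                "q2": model.metrics.q2,
            }

        if config.run_ad and model is not None:
            stage = "applicability_domain"
            ad = applicability_domain(
                model, table, y, residual_limit=config.residual_limit
            )
            write_table(ad.plot_data(), out / "applicability_domain.csv", stamp)
            manifest["stages"]["applicability_domain"] = {
                "h_star": ad.h_star,
                "counts": ad.counts,
            }

        if config.run_ale and model is not None:
            stage = "ale"
            profiles = ale_summary(model, table, grid_size=config.ale_grid_size)
            summary = {
                p.descriptor: {
                    "delta_range": list(p.delta_range),
                    "raw_delta_range": list(p.raw_delta_range),
                    "width": p.width,
                }
                for p in profiles
            }
            write_json(
                {"config_hash": config.config_hash, "grid_size": config.ale_grid_size,
                 "profiles": summary},
                out / "ale_summary.json",
            )
            manifest["stages"]["ale"] = {
                "largest_effect": profiles[0].descriptor,
                "grid_size": config.ale_grid_size,
            }

        if config.run_ensemble and table is not None:
            stage = "ensemble"
            ids = list(table.index)
            experimental = ids[: config.n_experimental]
            pool = ids[config.n_experimental:]
            plans = enumerate_pair_splits(
                experimental,
                pool,
                n_pool_test=config.n_pool_test,
                n_pool_train=min(config.n_pool_train, len(pool) - config.n_pool_test),
                seed=config.seed,
            )
            summary = run_ensemble(plans, table, y)
            write_table(summary.per_model, out / "ensemble.csv", stamp)
            manifest["stages"]["ensemble"] = {
                "n_models": summary.n_models,
                "mean_train_r2": summary.mean_train_r2,
                "mean_test_r2": summary.mean_test_r2,
                "mean_q2": summary.mean_q2,
            }

        if config.run_refinement and table is not None:
            stage = "refinement"
            traj = iterative_outlier_refinement(
                table,
                y,
                fractions=config.refinement_fractions,
                split_seed=config.seed,
            )
            write_table(traj.as_frame(), out / "refinement.csv", stamp)
            manifest["stages"]["refinement"] = {
                "fractions": list(config.refinement_fractions),
                "final_n": traj.rounds[-1].n_remaining,
                "final_train_r2": traj.rounds[-1].train_r2,
            }

        if config.run_contacts:
            stage = "contacts"
            rng = np.random.default_rng([config.seed, 99])
            contact_sets, per_complex = [], {}
            for k in range(config.n_complexes):
                planted = sorted(
                    rng.choice(
                        np.arange(1, config.n_residues + 1),
                        size=min(4, config.n_residues),
                        replace=False,
                    ).tolist()
                )
                cx = generate_complex(
                    config.n_residues,
                    planted,
                    cutoff=config.contact_cutoff,
                    seed=int(rng.integers(2**31)),
                    complex_id=f"complex-{k:02d}",
                )
                contacts = find_contacts(cx, cutoff=config.contact_cutoff)
                contact_sets.append(contacts)
                per_complex[cx.complex_id] = contacts
            profile = aggregate_frequencies(contact_sets)
            freq = pd.DataFrame(
                {"count": profile.counts, "percent": profile.percentages}
            )
            freq.index.name = "resname"
            write_table(freq, out / "contact_frequencies.csv", stamp)
            (out / "contacts.fasta").write_text(export_fasta(per_complex))
            manifest["stages"]["contacts"] = {
                "n_complexes": config.n_complexes,
                "total_contacts": profile.total,
            }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    write_json(manifest, out / "manifest.json")
    return manifest
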