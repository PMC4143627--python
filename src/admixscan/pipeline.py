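"""End-to-end synthetic pipeline: simulate -> AIMs -> generations -> scans
-> permutation -> power.

The pipeline runs entirely on simulated data with known ground truth and
writes every stage's output as a TSV dialect (see :mod:`admixscan.io`)
plus a YAML manifest recording the seed, stage completion and filter
counts.  A run with the same configuration is bit-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, aims, ancestry_metrics, io, mapping, powercalc, simpop

__all__ = ["PipelineConfig", "run_pipeline"]

_VALID_TRAITS = ("sbp", "dbp", "hyp")


@dataclass
class PipelineConfig:
    """Configuration of the synthetic end-to-end run.

    Defaults mirror the study conditions the package targets: a cohort
    of 109 individuals, three-way admixture centred at (0.6, 0.1, 0.3),
    10 generations since admixture on a 2.217-morgan chromosome, DBP as
    the analysis trait, and the dominant-model power design (MAF 5%, 36
    cases / 72 controls, alpha = 0.05/37,438).
    """

    # simulation
    n: int = 109
    n_snps: int = 2000
    g: float = 10.0
    mean_props: tuple[float, ...] = (0.6, 0.1, 0.3)
    concentration: float = 10.0
    divergence: tuple[float, ...] = (0.15, 0.15, 0.15)
    map_length_morgans: float = 2.217
    seed: int = 42
    # trait / scans
    trait: str = "dbp"
    log_transform: bool = True
    ancestry: str = "EUR"
    assoc_intercept: bool = False
    # AIM selection
    within_thresh: float = 0.1
    between_thresh: float = 0.2
    ld_cutoff: float = 0.1
    subpop_drift: float = 0.02
    # permutation
    perm_B: int = 200
    perm_threshold: float = 3.0
    perm_signed: bool = False
    # power design
    power_maf: float = 0.05
    power_grr: float = 14.4
    power_n_case: int = 36
    power_n_control: int = 72
    power_alpha: float = 0.05 / 37438

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("mean_props", "divergence"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.n < 4:
            raise ValueError("n must be at least 4 for the regression scans")
        if self.n_snps < 10:
            raise ValueError("n_snps must be at least 10")
        if self.trait not in _VALID_TRAITS:
            raise ValueError(f"trait must be one of {_VALID_TRAITS}")
        if self.g < 0:
            raise ValueError("g must be non-negative")
        if not 0 < self.within_thresh <= 1 or not 0 < self.between_thresh <= 1:
            raise ValueError("Fst thresholds must lie in (0, 1]")
        if not 0 < self.ld_cutoff <= 1:
            raise ValueError("ld_cutoff must lie in (0, 1]")
        if self.perm_B < 1:
            raise ValueError("perm_B must be at least 1")
        if len(self.mean_props) != 3 or len(self.divergence) != 3:
            raise ValueError("mean_props and divergence must have 3 entries")
        # power design bounds are enforced by PowerDesign itself
        powercalc.PowerDesign(
            maf=self.power_maf,
            grr=self.power_grr,
            n_case=self.power_n_case,
            n_control=self.power_n_control,
            alpha=self.power_alpha,
        )


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages, writing TSV artifacts and a manifest.

    Returns the manifest dictionary.  Any stage failure leaves earlier
    outputs on disk; the manifest marks which stages completed.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stages": {},
        "counts": {},
    }

    def done(stage: str, **counts) -> None:
        manifest["stages"][stage] = "complete"
        manifest["counts"].update(counts)
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)

    try:
        # -- simulate -------------------------------------------------------
        panel = simpop.draw_ancestral_freqs(
            config.n_snps,
            K=3,
            divergence=config.divergence,
            seed=seed,
            map_length_morgans=config.map_length_morgans,
        )
        cohort = simpop.simulate_cohort(
            panel,
            n=config.n,
            mean_props=config.mean_props,
            concentration=config.concentration,
            g=config.g,
            seed=seed,
        )
        io.write_map_tsv(outdir / "map.tsv", panel.gmap, seed=seed)
        io.write_genotypes_tsv(
            outdir / "genotypes.tsv",
            cohort.geno_dosage,
            panel.gmap.snp_ids,
            cohort.individual_ids,
            seed=seed,
        )
        io.write_local_ancestry(
            outdir / "local_ancestry.tsv", cohort.callset, seed=seed
        )
        io.write_phenotypes(outdir / "phenotypes.tsv", cohort.phenotypes, seed=seed)
        io.write_freq_table(
            outdir / "panel_freqs.tsv",
            pd.DataFrame(
                {"snp_id": panel.gmap.snp_ids}
                | {lab: panel.freqs[:, k] for k, lab in enumerate(panel.pop_labels)}
            ),
            seed=seed,
        )
        props = pd.DataFrame(
            cohort.global_props, columns=list(panel.pop_labels)
        )
        props.insert(0, "id", cohort.individual_ids)
        io._write_tsv(props, outdir / "global_props.tsv", seed=seed)
        done("simulate", n_individuals=config.n, n_snps=config.n_snps)

        # -- AIM selection ---------------------------------------------------
        aim_freqs = simpop.derive_subpop_freqs(
            panel, "NAM", drift=config.subpop_drift, seed=seed
        )
        io.write_freq_table(outdir / "aim_freqs.tsv", aim_freqs, seed=seed)
        panel_aims = aims.select_aims(
            aim_freqs,
            cohort.geno_dosage,
            panel.gmap,
            within_pops=("NAM1", "NAM2"),
            outgroup_pops=("EUR", "AFR"),
            within_thresh=config.within_thresh,
            between_thresh=config.between_thresh,
            ld_cutoff=config.ld_cutoff,
        )
        io._write_tsv(panel_aims.fst_table, outdir / "aims.tsv", seed=seed)
        done("select_aims", n_aims=int(panel_aims.n_selected))

        # -- generations since admixture ------------------------------------
        eur = panel.pop_labels.index(config.ancestry)
        seg = ancestry_metrics.count_segments(cohort.callset, target_pop=eur)
        n_gen_mean_a = ancestry_metrics.estimate_generations(
            seg.mean, config.mean_props[eur], panel.gmap.length_morgans
        )
        n_gen_per_ind = ancestry_metrics.estimate_generations(
            seg.counts,
            np.clip(cohort.global_props[:, eur], 1e-6, 1 - 1e-6),
            panel.gmap.length_morgans,
        )
        io._write_tsv(
            pd.DataFrame(
                {
                    "metric": [
                        "mean_segments",
                        "sd_segments",
                        "generations_cohort_mean_a",
                        "generations_per_individual_mean",
                        "true_generations",
                    ],
                    "value": [
                        seg.mean,
                        seg.sd,
                        n_gen_mean_a,
                        float(np.mean(n_gen_per_ind)),
                        config.g,
                    ],
                }
            ),
            outdir / "generations.tsv",
            seed=seed,
        )
        lengths = ancestry_metrics.tract_lengths_morgans(cohort.hap_paths, eur)
        hist, edges = np.histogram(lengths, bins=20)
        io._write_tsv(
            pd.DataFrame(
                {"bin_left_morgans": edges[:-1], "bin_right_morgans": edges[1:],
                 "count": hist}
            ),
            outdir / "tract_lengths.tsv",
            seed=seed,
        )
        done("estimate_generations", mean_segments=float(seg.mean))

        # -- scans -----------------------------------------------------------
        y = mapping.prepare_trait(
            cohort.phenotypes, config.trait, log_transform=config.log_transform
        )
        admix_engine = mapping.AdmixtureScanEngine(cohort.callset, config.ancestry)
        admix = admix_engine.scan(y)
        io._write_tsv(admix.to_frame(), outdir / "admixmap_scan.tsv", seed=seed)
        assoc = mapping.ancestry_adjusted_scan(
            y,
            cohort.geno_dosage,
            cohort.callset,
            panel.freqs,
            intercept=config.assoc_intercept,
        )
        io._write_tsv(assoc.to_frame(), outdir / "assoc_scan.tsv", seed=seed)
        done(
            "scans",
            admixmap_lambda=float(admix.lambda_gc),
            admixmap_significant=admix.n_significant,
            assoc_lambda=float(assoc.lambda_gc),
            assoc_significant=assoc.n_significant,
        )

        # -- permutation ------------------------------------------------------
        perm = mapping.permutation_excess_test(
            y,
            admix_engine,
            threshold=config.perm_threshold,
            B=config.perm_B,
            seed=seed,
            signed=config.perm_signed,
        )
        io._write_tsv(
            pd.DataFrame(
                {
                    "metric": ["threshold", "observed", "B", "p_value"],
                    "value": [perm.threshold, perm.observed, perm.B, perm.p_value],
                }
            ),
            outdir / "permutation.tsv",
            seed=seed,
        )
        done("permutation", permutation_p=float(perm.p_value))

        # -- power -------------------------------------------------------------
        design = powercalc.PowerDesign(
            maf=config.power_maf,
            grr=config.power_grr,
            n_case=config.power_n_case,
            n_control=config.power_n_control,
            alpha=config.power_alpha,
        )
        power = powercalc.power_two_prop(design)
        io._write_tsv(
            pd.DataFrame(
                {
                    "metric": [
                        "maf", "grr", "n_case", "n_control", "alpha",
                        "control_exposure", "power",
                    ],
                    "value": [
                        design.maf, design.grr, design.n_case, design.n_control,
                        design.alpha,
                        powercalc.dominant_exposure_prob(design.maf), power,
                    ],
                }
            ),
            outdir / "power.tsv",
            seed=seed,
        )
        done("power", power=float(power))
    except Exception:
        manifest["stages"]["failed"] = True
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        raise
    return manifest
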