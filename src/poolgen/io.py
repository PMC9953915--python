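"""Readers, writers, configuration and the end-to-end pipeline.

All tabular artifacts are delimited text (CSV/TSV) and structured results
are JSON; genotype states are the II/ID/DD strings of gel reads, with an
optional 0/1/2 dosage export for interoperability. The pipeline chains
herd simulation -> ME pooling design + screen -> population-genetic summary
-> association scan, with per-stage seeds derived from one global seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from poolgen import assoc, pooling, popgen
from poolgen.synth import GENOTYPES, HerdConfig, LocusSpec, TraitSpec, simulate_genotypes

log = logging.getLogger("poolgen")

# fixed offsets deriving per-stage seeds from the global seed
STAGE_SEED_OFFSETS = {"herd": 0, "pools": 101, "traits": 202}


def read_genotype_table(path, loci: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read and validate a genotype CSV (columns: id, sex, one per locus, traits).

    Genotype tokens must be II/ID/DD or empty; ids must be unique. Errors
    report the offending line number (header = line 1).
    """
    pop = pd.read_csv(path, dtype={"id": str}, keep_default_na=True)
    if "id" not in pop.columns:
        raise ValueError(f"{path}: missing required 'id' column")
    dup = pop["id"][pop["id"].duplicated()]
    if len(dup):
        line = int(dup.index[0]) + 2
        raise ValueError(f"{path}: duplicate id {dup.iloc[0]!r} at line {line}")
    if loci is None:
        loci = [
            c
            for c in pop.columns
            if c not in ("id", "sex") and set(pop[c].dropna().astype(str)) <= set(GENOTYPES)
        ]
    for locus in loci:
        if locus not in pop.columns:
            raise ValueError(f"{path}: missing locus column {locus!r}")
        bad = pop[locus].dropna()[~pop[locus].dropna().isin(GENOTYPES)]
        if len(bad):
            line = int(bad.index[0]) + 2
            raise ValueError(
                f"{path}: invalid genotype token {bad.iloc[0]!r} in column {locus!r} at line {line}"
            )
    log.info("read %d individuals from %s (loci: %s)", len(pop), path, list(loci))
    return pop


def write_population(pop: pd.DataFrame, path) -> None:
    """Write a herd table as CSV with empty fields for missing values."""
    pop.to_csv(path, index=False)


def dosage_table(pop: pd.DataFrame, loci: Sequence[str], mutant_alleles: Mapping[str, str]) -> pd.DataFrame:
    """Export genotypes as 0/1/2 mutant-allele dosages for interoperability."""
    out = pop.copy()
    for locus in loci:
        mut = mutant_alleles[locus]
        out[locus] = pop[locus].map(lambda g: g.count(mut) if isinstance(g, str) else pd.NA)
    return out


def herd_config_from_dict(doc: Mapping) -> HerdConfig:
    """Build a :class:`HerdConfig` from a parsed YAML/JSON document."""
    loci = [
        LocusSpec(name=d["name"], mutant_allele=d["mutant_allele"], mutant_freq=float(d["mutant_freq"]))
        for d in doc["loci"]
    ]
    traits = [
        TraitSpec(
            name=t["name"],
            locus=t["locus"],
            genotype_params={
                g: (float(v["mean"]), float(v["se"]), int(v["n"]))
                for g, v in t["genotypes"].items()
            },
            sex_restriction=t.get("sex"),
            missing_rate=float(t.get("missing_rate", 0.0)),
        )
        for t in doc.get("traits", [])
    ]
    return HerdConfig(
        n_individuals=int(doc["n_individuals"]),
        sex_counts={k: int(v) for k, v in doc["sex_counts"].items()},
        loci=loci,
        d_prime=float(doc.get("d_prime", 0.0)),
        coupling=doc.get("coupling", "mutant"),
        trait_specs=traits,
        seed=int(doc.get("seed", 0)),
    )


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    herd: HerdConfig
    pooling: Mapping[str, Mapping]  # locus -> {carrier_freq, n_max, fp_rate, fn_rate}
    association: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        locus_names = {loc.name for loc in self.herd.loci}
        unknown = set(self.pooling) - locus_names
        if unknown:
            raise ValueError(f"pooling config references unknown loci: {sorted(unknown)}")
        alphas = self.association.get("alphas", (0.05, 0.01))
        if not all(0 < a < 1 for a in alphas):
            raise ValueError("alpha levels must lie in (0, 1)")


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    herd_doc = dict(doc["herd"])
    seed = int(doc.get("seed", herd_doc.get("seed", 0)))
    herd_doc["seed"] = seed + STAGE_SEED_OFFSETS["herd"]
    return PipelineConfig(
        herd=herd_config_from_dict(herd_doc),
        pooling=doc.get("pooling", {}),
        association=doc.get("association", {}),
        seed=seed,
    )


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run simulate -> design/run pools -> popgen -> association and write the bundle.

    Writes herd CSV, per-locus ME design JSON + pool outcome TSV, a locus
    summary TSV, an LD JSON (two-locus herds), association TSVs and a run
    manifest. Identical config + seed reproduce the bundle byte for byte.
    Stage failures raise with the stage name; artifacts already written stay
    on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": [], "parameters": {}}
    mutant_alleles = {loc.name: loc.mutant_allele for loc in config.herd.loci}

    def stage(name):
        log.info("pipeline stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("simulate")
        pop = simulate_genotypes(config.herd)
        write_population(pop, outdir / "herd.csv")

        stage("pooling")
        designs = {}
        for locus, cfg in config.pooling.items():
            design = pooling.optimal_pool_size(
                N=config.herd.n_individuals,
                p=float(cfg["carrier_freq"]),
                n_max=int(cfg.get("n_max", 64)),
            )
            designs[locus] = design.__dict__
            plan = pooling.make_pools(pop["id"], design.n_opt)
            outcome = pooling.run_pools(
                plan,
                pop,
                locus,
                mutant_allele=mutant_alleles[locus],
                fp_rate=float(cfg.get("fp_rate", 0.0)),
                fn_rate=float(cfg.get("fn_rate", 0.0)),
                seed=config.seed + STAGE_SEED_OFFSETS["pools"],
            )
            calls = outcome.calls.rename("called_genotype").rename_axis("individual_id").reset_index()
            calls.to_csv(outdir / f"pools_{locus}.tsv", sep="\t", index=False)
            designs[locus]["realized_rt"] = outcome.realized_rt
            designs[locus]["reduction"] = outcome.reduction
        with open(outdir / "me_design.json", "w") as fh:
            json.dump(designs, fh, indent=2)

        stage("popgen")
        locus_names = [loc.name for loc in config.herd.loci]
        popgen.locus_table(pop, locus_names).to_csv(outdir / "locus_summary.tsv", sep="\t", index=False)
        if len(locus_names) == 2:
            try:
                ld = popgen.em_haplotypes(popgen.two_locus_counts(pop, *locus_names))
                with open(outdir / "ld.json", "w") as fh:
                    json.dump(
                        {
                            "haplotype_freqs": dict(ld.haplotype_freqs),
                            "D": ld.d,
                            "D_prime": ld.d_prime,
                            "r2": ld.r2,
                            "em_iterations": ld.em_iterations,
                        },
                        fh,
                        indent=2,
                    )
            except popgen.MonomorphicLocusError as exc:
                log.warning("LD skipped: %s", exc)

        stage("association")
        traits = config.association.get("traits", [s.name for s in config.herd.trait_specs])
        loci = config.association.get("loci", locus_names)
        rows = assoc.association_scan(
            pop,
            loci=loci,
            traits=traits,
            stratify_by_sex=bool(config.association.get("by_sex", False)),
        )
        table = assoc.rows_to_frame(rows, fdr=bool(config.association.get("fdr", False)))
        table.to_csv(outdir / "association.tsv", sep="\t", index=False)

        manifest["parameters"] = {
            "n_individuals": config.herd.n_individuals,
            "loci": locus_names,
            "pooling": {k: dict(v) for k, v in config.pooling.items()},
            "traits": list(traits),
        }
        import poolgen

        manifest["versions"] = {"poolgen": poolgen.__version__, "pandas": pd.__version__}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {manifest['stages'][-1]!r}: {exc}") from exc
    return manifest
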