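"""File formats, run configuration and the command-line interface.

Formats:

* FASTA for sequences (Biopython): TF records carry their id and role in
  the header (``>TF1 role=input``), cis regions the id ``cis``.
* TSV for tabular data: the 20x4 energy matrix (rows = amino acids in
  alphabetical one-letter order, columns A/C/G/T, kT units), the 12x4
  promoter model (rows = hexamer positions -35..-30 then -12..-7), run
  logs and exported curves.
* BED for called binding sites (0-based half-open intervals,
  name = ``tf:role``, score = round(1000 * O_max)).
* JSON for run configuration and analysis summaries.

All writers produce files their readers parse back to equal objects.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evolutionary_engine import EvolutionConfig, RunLog, evolve
from .gates_and_fitness import EvaluationGrid, FitnessWeights, GateSpec
from .promoter_analysis import (
    SiteCall,
    call_binding_sites,
    feedback_measure,
    footprint,
)
from .response_dynamics import DynamicsParams, ModelSet
from .sequence_energetics import (
    AMINO_ACIDS,
    NUCLEOTIDES,
    CisRegion,
    EnergyMatrix,
    PromoterModel,
    TranscriptionFactor,
)
from .thermodynamic_model import Genotype, ThermoParams

__all__ = [
    "RunConfig",
    "read_energy_matrix",
    "write_energy_matrix",
    "read_promoter_model",
    "write_promoter_model",
    "read_genotype",
    "write_genotype",
    "write_site_calls_bed",
    "write_run_log",
    "cli",
]


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------


def write_energy_matrix(matrix: EnergyMatrix, path) -> None:
    df = pd.DataFrame(matrix.entries, index=list(AMINO_ACIDS), columns=list(NUCLEOTIDES))
    df.to_csv(path, sep="\t", index_label="aa", float_format="%.10g")


def read_energy_matrix(path) -> EnergyMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape != (20, 4):
        raise ValueError(f"{path}: energy matrix must be 20x4, got {df.shape}")
    if list(df.index) != list(AMINO_ACIDS) or list(df.columns) != list(NUCLEOTIDES):
        raise ValueError(f"{path}: rows must be the 20 amino acids, columns A/C/G/T")
    values = df.to_numpy(dtype=float)
    lo = min(-3.0, float(values.min()))
    hi = max(3.0, float(values.max()))
    return EnergyMatrix(entries=values, provenance=str(path), value_range=(lo, hi))


def write_promoter_model(pm: PromoterModel, path) -> None:
    positions = [*range(-35, -29), *range(-12, -6)]
    df = pd.DataFrame(pm.scores, index=positions, columns=list(NUCLEOTIDES))
    df.to_csv(path, sep="\t", index_label="position", float_format="%.10g")


def read_promoter_model(path) -> PromoterModel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape != (12, 4):
        raise ValueError(f"{path}: promoter model must be 12x4, got {df.shape}")
    return PromoterModel(scores=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Genotypes: FASTA + JSON metadata
# ---------------------------------------------------------------------------


def write_genotype(genotype: Genotype, path) -> None:
    records = [SeqRecord(Seq(genotype.cis.sequence), id="cis", description="")]
    for tf in genotype.tfs:
        records.append(
            SeqRecord(Seq(tf.sequence), id=tf.id, description=f"role={tf.role}")
        )
    SeqIO.write(records, str(path), "fasta")


def read_genotype(path) -> Genotype:
    cis = None
    tfs: dict[str, TranscriptionFactor] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id == "cis":
            cis = CisRegion(str(record.seq))
        elif record.id in ("TF1", "TF2", "TF3"):
            role = "input"
            for token in record.description.split():
                if token.startswith("role="):
                    role = token.split("=", 1)[1]
            tfs[record.id] = TranscriptionFactor(record.id, str(record.seq), role=role)
    missing = {"TF1", "TF2", "TF3"} - set(tfs)
    if cis is None or missing:
        raise ValueError(f"{path}: genotype FASTA needs records cis, TF1, TF2, TF3")
    return Genotype(cis=cis, tf1=tfs["TF1"], tf2=tfs["TF2"], tf3=tfs["TF3"])


def write_population_fasta(population: list[Genotype], path) -> None:
    records = []
    for i, g in enumerate(population):
        records.append(SeqRecord(Seq(g.cis.sequence), id=f"g{i}|cis", description=""))
        for tf in g.tfs:
            records.append(
                SeqRecord(Seq(tf.sequence), id=f"g{i}|{tf.id}",
                          description=f"role={tf.role}")
            )
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED site calls and run logs
# ---------------------------------------------------------------------------


def write_site_calls_bed(calls: list[SiteCall], path, chrom: str = "cis") -> None:
    with open(path, "w") as fh:
        for call in calls:
            score = int(round(1000 * call.o_max))
            fh.write(
                f"{chrom}\t{call.start}\t{call.end}\t{call.tf_id}:{call.role}\t{score}\t+\n"
            )


def read_site_calls_bed(path) -> list[SiteCall]:
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: malformed BED line")
            tf_id, role = fields[3].split(":", 1)
            calls.append(
                SiteCall(
                    tf_id=tf_id,
                    start=int(fields[1]),
                    end=int(fields[2]),
                    o_max=int(fields[4]) / 1000.0,
                    role=role,
                )
            )
    return calls


def run_log_frame(log: RunLog) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cycle": log.cycle,
            "best_s": log.best_s,
            "median_s": log.median_s,
            "best_e_rf": log.best_e_rf,
            "best_e_rt": log.best_e_rt,
            "best_e_n": log.best_e_n,
            "best_feedback": log.best_feedback,
        }
    )


def write_run_log(log: RunLog, path) -> None:
    run_log_frame(log).to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one run.

    Round-trips losslessly through JSON; every field has a default, so a
    config file only needs to state deviations from the study conditions.
    """

    gate: str = "ACT"
    seed: int = 0
    population_size: int = 200
    cycles: int = 1000
    survivor_fraction: float = 0.2
    p_sub: float = 0.5
    p_indel: float = 0.1
    p_tf: float = 0.03
    l_cis: int = 150
    l_tf: int = 9
    thermo: ThermoParams = dataclasses.field(default_factory=ThermoParams)
    dynamics: DynamicsParams = dataclasses.field(default_factory=DynamicsParams)
    weights: FitnessWeights = dataclasses.field(default_factory=FitnessWeights)
    matrix_path: str | None = None
    promoter_model_path: str | None = None
    matrix_seed: int = 0
    specificity: float = 3.0
    out_dir: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        for name, typ in (
            ("thermo", ThermoParams),
            ("dynamics", DynamicsParams),
            ("weights", FitnessWeights),
        ):
            if name in raw and isinstance(raw[name], dict):
                raw[name] = typ(**raw[name])
        return cls(**raw)

    def models(self) -> ModelSet:
        from .fixtures import consensus_promoter_model, make_synthetic_matrix

        matrix = (
            read_energy_matrix(self.matrix_path)
            if self.matrix_path
            else make_synthetic_matrix(self.matrix_seed, self.specificity)
        )
        pm = (
            read_promoter_model(self.promoter_model_path)
            if self.promoter_model_path
            else consensus_promoter_model()
        )
        return ModelSet(matrix, pm, self.thermo, self.dynamics)

    def evolution_config(self) -> EvolutionConfig:
        return EvolutionConfig(
            gate=GateSpec(self.gate),
            population_size=self.population_size,
            cycles=self.cycles,
            survivor_fraction=self.survivor_fraction,
            p_sub=self.p_sub,
            p_indel=self.p_indel,
            p_tf=self.p_tf,
            seed=self.seed,
            l_cis=self.l_cis,
            l_tf=self.l_tf,
            weights=self.weights,
        )


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
def cli() -> None:
    """Evolutionary design of cis-regulatory regions with auto-regulation."""


@cli.command("evolve")
@click.option("--gate", default="ACT", show_default=True)
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--pop", "population_size", default=200, show_default=True, type=int)
@click.option("--cycles", default=1000, show_default=True, type=int)
@click.option("--lambda-rt", default=0.0, show_default=True, type=float)
@click.option("--lambda-noise", default=0.0, show_default=True, type=float)
@click.option("--l-cis", default=150, show_default=True, type=int)
@click.option("--out", "out_dir", required=True, type=click.Path(file_okay=False))
def cli_evolve(gate, seed, population_size, cycles, lambda_rt, lambda_noise, l_cis, out_dir):
    """Run the evolutionary algorithm and write the run log and population."""
    config = RunConfig(
        gate=gate, seed=seed, population_size=population_size, cycles=cycles,
        l_cis=l_cis,
        weights=FitnessWeights(lambda_rt_max=lambda_rt, lambda_noise_max=lambda_noise),
        out_dir=out_dir,
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = evolve(config.evolution_config(), config.models())
    write_run_log(log, out / "runlog.tsv")
    write_population_fasta(log.final_population, out / "population.fasta")
    (out / "config.json").write_text(config.to_json())
    best = log.best_genotype
    write_genotype(best, out / "best.fasta")
    click.echo(f"best E_RF = {log.best_e_rf[-1]:.6g} after {cycles} cycles")


@cli.command("analyze")
@click.option("--genotype", "genotype_path", required=True, type=click.Path(exists=True))
@click.option("--gate", default="NAND", show_default=True)
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--threshold", default=0.5, show_default=True, type=float)
@click.option("--out", "out_dir", required=True, type=click.Path(file_okay=False))
def cli_analyze(genotype_path, gate, seed, threshold, out_dir):
    """Feedback measure, footprint and binding-site calls for a genotype."""
    from .fixtures import default_models

    models = default_models(seed)
    genotype = read_genotype(genotype_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gate_spec = GateSpec(gate)
    f_value = feedback_measure(genotype, models, EvaluationGrid(), gate_spec)
    profile = footprint(genotype, models)
    table = models.site_table(genotype)
    calls = call_binding_sites(profile, table, threshold)
    write_site_calls_bed(calls, out / "sites.bed")
    (out / "summary.json").write_text(
        json.dumps(
            {"feedback_measure_nM2": f_value, "n_sites": len(calls), "gate": gate},
            indent=2,
        )
    )
    click.echo(f"F = {f_value:.6g} nM^2, {len(calls)} called site(s)")


@cli.command("footprint")
@click.option("--genotype", "genotype_path", required=True, type=click.Path(exists=True))
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--out", "out_path", required=True, type=click.Path(dir_okay=False))
def cli_footprint(genotype_path, seed, out_path):
    """Write the per-site O_max footprint profile as TSV."""
    from .fixtures import default_models

    models = default_models(seed)
    profile = footprint(read_genotype(genotype_path), models)
    df = pd.DataFrame(profile.o_max.T, columns=["TF1", "TF2", "TF3"])
    df.insert(0, "start", np.arange(profile.o_max.shape[1]))
    df.to_csv(out_path, sep="\t", index=False, float_format="%.6g")
    click.echo(f"wrote {out_path}")


@cli.command("minimal")
@click.option("--layout", default="rep_2site_coop", show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path(dir_okay=False))
@click.option("--k3", default=None, type=float)
def cli_minimal(layout, out_path, k3):
    """Maximal-sensitivity sweep of a minimal model; writes a JSON summary."""
    from .minimal_models import max_sensitivity

    result = max_sensitivity(layout, k3=k3, points_per_decade=10, c1_points=101)
    Path(out_path).write_text(json.dumps(result, indent=2))
    click.echo(f"S_max = {result['s_max']:.4f}")


@cli.command("fixtures")
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--out", "out_dir", required=True, type=click.Path(file_okay=False))
def cli_fixtures(seed, out_dir):
    """Emit the synthetic matrix, promoter model and reference designs."""
    from .fixtures import (
        REFERENCE_DESIGNS,
        consensus_promoter_model,
        default_models,
        make_synthetic_matrix,
        random_genotype,
        reference_design,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_energy_matrix(make_synthetic_matrix(seed), out / "energy_matrix.tsv")
    write_promoter_model(consensus_promoter_model(), out / "promoter_model.tsv")
    write_genotype(random_genotype(seed), out / "random_genotype.fasta")
    # reference designs are tuned against the default study conditions
    models = default_models(0)
    for name in REFERENCE_DESIGNS:
        write_genotype(reference_design(name, models=models), out / f"{name}.fasta")
    click.echo(f"fixtures written to {out}")


def main(argv=None) -> int:
    try:
        cli.main(args=argv, standalone_mode=False)
    except click.ClickException as exc:
        exc.show()
        return exc.exit_code
    except click.Abort:
        return 1
    return 0


if __name__ == "__main__":  # pragma: no cover
    sys.exit(main())
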