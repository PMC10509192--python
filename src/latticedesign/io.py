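"""File formats and configuration: conformations, YAML task configs, FASTA, reports.

Residue positions are 0-based everywhere inside the library; config files
and the CLI use 1-based residue numbers (the biology convention) and are
converted at this boundary. Unknown config keys are hard errors -- silent
misconfiguration is the main reproducibility hazard.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .decode import BAYES_RATIO, BOLTZMANN, CONDITIONAL_ONLY, DecodeResult
from .exceptions import ValidationError
from .fixtures import MAX_CONTACTS_NATIVE, pick_native
from .lattice import (
    Alphabet,
    Conformation,
    ContactPotential,
    EnsembleModel,
    canonicalize,
)
from .models import JointModel, SequencePrior
from .tasks import DesignConstraints, DesignTask, random_order

CONFORMATION_HEADER = "# lattice-conformation v1"


# ---------------------------------------------------------------- conformations

def write_conformation(conformation: Conformation, path) -> None:
    """Plain-text conformation file: a length line then one `x y` line per monomer."""
    lines = [CONFORMATION_HEADER, f"length: {conformation.length}"]
    lines += [f"{x} {y}" for x, y in conformation.coords]
    Path(path).write_text("\n".join(lines) + "\n")


def read_conformation(path) -> Conformation:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or lines[0] != CONFORMATION_HEADER:
        raise ValidationError(f"{path}: not a lattice-conformation file")
    if not lines[1].startswith("length:"):
        raise ValidationError(f"{path}: missing length line")
    length = int(lines[1].split(":", 1)[1])
    coords = []
    for ln in lines[2:]:
        x, y = ln.split()
        coords.append((int(x), int(y)))
    if len(coords) != length:
        raise ValidationError(f"{path}: expected {length} coordinates, got {len(coords)}")
    return Conformation(tuple(coords))


def write_ensemble(conformations: Sequence[Conformation], path) -> None:
    """Concatenated conformation records separated by blank lines."""
    blocks = []
    for conf in conformations:
        lines = [CONFORMATION_HEADER, f"length: {conf.length}"]
        lines += [f"{x} {y}" for x, y in conf.coords]
        blocks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(blocks) + "\n")


# ----------------------------------------------------------------- task config

_TOP_KEYS = {
    "length",
    "alphabet",
    "energy_matrix",
    "kT",
    "prior",
    "mismatched_prior",
    "native",
    "constraints",
    "decoders",
    "seed",
}
_PRIOR_KEYS = {"kind", "initial", "transition"}
_NATIVE_KEYS = {"coords", "rule"}
_CONSTRAINT_KEYS = {"fixed", "order", "order_seed"}
_DECODER_KEYS = {"name", "type", "objective", "width"}


def _reject_unknown(mapping: Mapping, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValidationError(f"unknown {context} config keys: {sorted(unknown)}")


@dataclass(frozen=True)
class DecoderSpec:
    name: str
    type: str  # greedy | beam | brute_force
    objective: str = BAYES_RATIO
    width: int = 1


@dataclass(frozen=True)
class TaskConfig:
    """Parsed, validated design-task configuration."""

    length: int
    alphabet: str
    energy_matrix: tuple[tuple[float, ...], ...]
    kT: float
    prior: SequencePrior
    mismatched_prior: SequencePrior | None
    native_coords: tuple[tuple[int, int], ...] | None  # None -> auto rule
    native_rule: str | None
    fixed: tuple[tuple[int, str], ...]  # 0-based
    order: str  # identity | random
    order_seed: int
    decoders: tuple[DecoderSpec, ...]
    seed: int

    def build(self) -> tuple[DesignTask, JointModel]:
        alphabet = Alphabet.from_string(self.alphabet)
        potential = ContactPotential.from_matrix(alphabet, self.energy_matrix)
        model = EnsembleModel.build(self.length, alphabet, potential, kT=self.kT)
        if self.native_coords is not None:
            native = canonicalize(self.native_coords)
            if native.length != self.length:
                raise ValidationError("native conformation length differs from task length")
            try:
                native_index = model.conformations.index(native)
            except ValueError:
                raise ValidationError("native conformation not in the ensemble") from None
        else:
            native_index = pick_native(
                model, self.native_rule or MAX_CONTACTS_NATIVE, np.random.default_rng(0)
            )
        order = None
        if self.order == "random":
            order = random_order(self.length, np.random.default_rng(self.order_seed))
        constraints = DesignConstraints.create(dict(self.fixed), order)
        return DesignTask(model, native_index, constraints), JointModel(self.prior, model)


def _prior_to_dict(prior: SequencePrior) -> dict:
    if prior.kind == "uniform":
        return {"kind": "uniform"}
    return {
        "kind": "markov1",
        "initial": [float(p) for p in prior.initial],
        "transition": [[float(p) for p in row] for row in prior.transition],
    }


def fixture_to_config(
    task: DesignTask, joint: JointModel, seed: int = 0
) -> TaskConfig:
    """Serializable TaskConfig describing a generated task (native given inline)."""
    model = task.model
    return TaskConfig(
        length=model.length,
        alphabet=str(model.alphabet),
        energy_matrix=model.potential.energies,
        kT=model.kT,
        prior=joint.prior,
        mismatched_prior=None,
        native_coords=task.native.coords,
        native_rule=None,
        fixed=task.constraints.fixed,
        order="identity",
        order_seed=0,
        decoders=(
            DecoderSpec("greedy_bayes_ratio", "greedy", BAYES_RATIO, 1),
            DecoderSpec("greedy_conditional_only", "greedy", CONDITIONAL_ONLY, 1),
        ),
        seed=seed,
    )


def _parse_prior(raw: Mapping, alphabet: Alphabet, context: str) -> SequencePrior:
    _reject_unknown(raw, _PRIOR_KEYS, context)
    kind = raw.get("kind", "uniform")
    if kind == "uniform":
        return SequencePrior.uniform(alphabet)
    if kind == "markov1":
        return SequencePrior.markov1(alphabet, raw["initial"], raw["transition"])
    raise ValidationError(f"unknown prior kind {kind!r}")


def parse_task_config(raw: Mapping) -> TaskConfig:
    if not isinstance(raw, Mapping):
        raise ValidationError("task config must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "top-level")
    for key in ("length", "alphabet", "energy_matrix"):
        if key not in raw:
            raise ValidationError(f"task config missing required key {key!r}")
    length = int(raw["length"])
    alphabet = Alphabet.from_string(str(raw["alphabet"]))
    matrix = tuple(tuple(float(v) for v in row) for row in raw["energy_matrix"])
    prior = _parse_prior(raw.get("prior", {"kind": "uniform"}), alphabet, "prior")
    mismatched = (
        _parse_prior(raw["mismatched_prior"], alphabet, "mismatched_prior")
        if "mismatched_prior" in raw
        else None
    )

    native_raw = raw.get("native", {"rule": MAX_CONTACTS_NATIVE})
    _reject_unknown(native_raw, _NATIVE_KEYS, "native")
    native_coords = native_rule = None
    if "coords" in native_raw:
        native_coords = tuple((int(x), int(y)) for x, y in native_raw["coords"])
    else:
        native_rule = str(native_raw.get("rule", MAX_CONTACTS_NATIVE))

    cons_raw = raw.get("constraints", {})
    _reject_unknown(cons_raw, _CONSTRAINT_KEYS, "constraints")
    fixed = {}
    for pos, sym in (cons_raw.get("fixed") or {}).items():
        pos = int(pos)
        if pos < 1:
            raise ValidationError("fixed residue numbers are 1-based in config files")
        fixed[pos - 1] = str(sym)
    order = str(cons_raw.get("order", "identity"))
    if order not in ("identity", "random"):
        raise ValidationError("constraints.order must be 'identity' or 'random'")

    decoders_raw = raw.get(
        "decoders",
        [
            {"type": "greedy", "objective": BAYES_RATIO},
            {"type": "greedy", "objective": CONDITIONAL_ONLY},
        ],
    )
    decoders = []
    for d in decoders_raw:
        _reject_unknown(d, _DECODER_KEYS, "decoder")
        dtype = str(d.get("type", "greedy"))
        if dtype not in ("greedy", "beam", "brute_force"):
            raise ValidationError(f"unknown decoder type {dtype!r}")
        objective = str(d.get("objective", BAYES_RATIO))
        if objective not in (BAYES_RATIO, CONDITIONAL_ONLY, BOLTZMANN):
            raise ValidationError(f"unknown objective {objective!r}")
        if objective == BOLTZMANN and dtype != "brute_force":
            raise ValidationError("the boltzmann objective is only exhaustively decodable")
        decoders.append(
            DecoderSpec(
                name=str(d.get("name", f"{dtype}_{objective}")),
                type=dtype,
                objective=objective,
                width=int(d.get("width", 1)),
            )
        )

    return TaskConfig(
        length=length,
        alphabet=str(alphabet),
        energy_matrix=matrix,
        kT=float(raw.get("kT", 1.0)),
        prior=prior,
        mismatched_prior=mismatched,
        native_coords=native_coords,
        native_rule=native_rule,
        fixed=tuple(sorted(fixed.items())),
        order=order,
        order_seed=int(cons_raw.get("order_seed", 0)),
        decoders=tuple(decoders),
        seed=int(raw.get("seed", 0)),
    )


def load_task_config(path) -> TaskConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return parse_task_config(raw)


def task_config_to_dict(cfg: TaskConfig) -> dict:
    """Round-trippable plain-dict form of a TaskConfig (1-based fixed positions)."""
    out: dict = {
        "length": cfg.length,
        "alphabet": cfg.alphabet,
        "energy_matrix": [list(row) for row in cfg.energy_matrix],
        "kT": cfg.kT,
        "prior": _prior_to_dict(cfg.prior),
        "seed": cfg.seed,
    }
    if cfg.mismatched_prior is not None:
        out["mismatched_prior"] = _prior_to_dict(cfg.mismatched_prior)
    out["native"] = (
        {"coords": [list(pt) for pt in cfg.native_coords]}
        if cfg.native_coords is not None
        else {"rule": cfg.native_rule}
    )
    out["constraints"] = {
        "fixed": {pos + 1: sym for pos, sym in cfg.fixed},
        "order": cfg.order,
        "order_seed": cfg.order_seed,
    }
    out["decoders"] = [
        {"name": d.name, "type": d.type, "objective": d.objective, "width": d.width}
        for d in cfg.decoders
    ]
    return out


def write_task_config(cfg: TaskConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(task_config_to_dict(cfg), sort_keys=True))


def config_hash(cfg: TaskConfig) -> str:
    """Short digest of the canonical config dump; embedded in output artifacts."""
    dump = yaml.safe_dump(task_config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(dump.encode()).hexdigest()[:12]


# ----------------------------------------------------------------------- FASTA

def write_fasta(
    results: Iterable[tuple[str, DecodeResult, Mapping]],
    path,
) -> None:
    """Write decode results as FASTA (60-column wrap).

    Each item is (record name, DecodeResult, metadata); metadata key/value
    pairs (decoder, scores, seed, config hash, ...) go into the record
    description as space-separated `key=value` fields.
    """
    records = []
    for name, result, meta in results:
        fields = {"objective": result.objective_name, **meta}
        fields.setdefault("objective_total", f"{result.objective_total:.6f}")
        desc = " ".join(f"{k}={v}" for k, v in fields.items())
        records.append(SeqRecord(Seq(result.sequence), id=name, description=desc))
    try:
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    except OSError as exc:
        raise ValidationError(f"cannot write FASTA to {path}: {exc}") from exc


def read_fasta_sequences(path) -> list[tuple[str, str]]:
    try:
        with open(path) as fh:
            return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
    except OSError as exc:
        raise ValidationError(f"cannot read FASTA from {path}: {exc}") from exc


# ---------------------------------------------------------------------- tables

def write_table(frame: pd.DataFrame, path) -> None:
    """Tab-separated report with a header row."""
    frame.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
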