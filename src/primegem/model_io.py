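"""Metabolic model and omics input/output.

This module owns the in-memory representation of a constraint-based
metabolic model (stoichiometry ``S``, flux bounds, gene-reaction mapping,
biomass objective, exchange reactions) and every format dialect the
package reads or writes:

* SBML Level 3 + FBC, through cobrapy/libsbml;
* a documented JSON schema (see :func:`write_model`), lossless for
  bounds, stoichiometry, gene sets and the objective;
* a single-file tabular (TSV) dialect for hand-written toy models;
* TSV/CSV gene-expression matrices, phenotype vectors and media tables.

It also provides the two model transforms every later stage relies on:
decomposition of reversible reactions into irreversible forward/backward
copies (:func:`split_reversible`) and the gene-to-reaction expression
mapping (:func:`reaction_expression`), which scores each reaction with
the arithmetic mean expression of its catalyzing enzymes.  Boolean
AND/OR gene-association structure is retained verbatim on the reaction
(``gpr``) but never evaluated.

Sign convention: on unsplit models uptake is a *negative* flux through an
exchange reaction (stoichiometry ``{met: -1}``); after splitting, all
fluxes are nonnegative and the backward copy of an exchange carries the
uptake.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PrimegemError(Exception):
    """Base class for all package errors."""


class ModelFormatError(PrimegemError):
    """A model file could not be parsed under the named dialect."""


class ModelInvalidError(PrimegemError):
    """A parsed model violates a structural invariant (e.g. lb > ub)."""


class MediaError(PrimegemError):
    """A media definition references a reaction that is not an exchange."""


class EmptyMappingError(PrimegemError):
    """No gene of the model appears in the expression matrix."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: Optional[str] = None


@dataclass
class Reaction:
    """One reaction: sparse stoichiometry plus bounds and gene set.

    ``stoichiometry`` maps metabolite id to its (signed) coefficient;
    negative coefficients are consumed, positive produced.  ``genes`` is
    the flattened set of catalyzing genes; ``gpr`` keeps the original
    boolean rule as text.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float
    upper_bound: float
    genes: FrozenSet[str] = frozenset()
    gpr: str = ""

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoichiometry), self.lower_bound,
                        self.upper_bound, frozenset(self.genes), self.gpr)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class MetabolicModel:
    """A genome-scale metabolic model at steady state (S v = 0, lb <= v <= ub)."""

    id: str
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    objective: str
    exchanges: FrozenSet[str] = frozenset()
    #: original reaction id -> (forward id, backward id or None); filled by
    #: :func:`split_reversible`, identity for never-split models.
    split_map: Dict[str, Tuple[str, Optional[str]]] = field(default_factory=dict)

    # -- lookups ------------------------------------------------------------

    def reaction(self, rid: str) -> Reaction:
        try:
            return self._index()[rid]
        except KeyError:
            raise KeyError(f"unknown reaction id {rid!r} in model {self.id!r}")

    def _index(self) -> Dict[str, Reaction]:
        # rebuilt lazily; invalidated by copy(), cheap at the scales used here
        idx = getattr(self, "_ridx", None)
        if idx is None or len(idx) != len(self.reactions):
            idx = {r.id: r for r in self.reactions}
            object.__setattr__(self, "_ridx", idx)
        return idx

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def genes(self) -> FrozenSet[str]:
        out: set = set()
        for r in self.reactions:
            out |= r.genes
        return frozenset(out)

    def reactions_by_gene(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for r in self.reactions:
            for g in r.genes:
                out.setdefault(g, []).append(r.id)
        return out

    def is_exchange(self, rid: str) -> bool:
        return rid in self.exchanges

    def is_transport(self, rid: str) -> bool:
        """True if the reaction moves a metabolite across compartments."""
        comps = set()
        for mid in self.reaction(rid).stoichiometry:
            met = next((m for m in self.metabolites if m.id == mid), None)
            comps.add(met.compartment if met is not None else None)
        return len(comps) > 1

    # -- lifecycle ----------------------------------------------------------

    def copy(self) -> "MetabolicModel":
        m = MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            objective=self.objective,
            exchanges=frozenset(self.exchanges),
            split_map=dict(self.split_map),
        )
        return m

    def validate(self) -> "MetabolicModel":
        """Check structural invariants; raise :class:`ModelInvalidError`."""
        mids = set(self.metabolite_ids)
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ModelInvalidError(f"duplicate reaction ids in model {self.id!r}")
        if len(mids) != len(self.metabolites):
            raise ModelInvalidError(f"duplicate metabolite ids in model {self.id!r}")
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise ModelInvalidError(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} exceeds "
                    f"upper bound {r.upper_bound}")
            for mid in r.stoichiometry:
                if mid not in mids:
                    raise ModelFormatError(
                        f"reaction {r.id!r} references undeclared metabolite {mid!r}")
        if self.objective not in set(rids):
            raise ModelInvalidError(
                f"objective reaction {self.objective!r} not in model {self.id!r}")
        for rid in self.exchanges:
            if rid not in set(rids):
                raise ModelInvalidError(f"exchange id {rid!r} not in model")
            nz = [c for c in self.reaction(rid).stoichiometry.values() if c != 0]
            if len(nz) > 1:
                raise ModelInvalidError(
                    f"exchange reaction {rid!r} has more than one metabolite")
        return self


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------
#
# Schema (all keys required unless noted):
# {
#   "id": str,
#   "metabolites": [{"id": str, "compartment": str|null}],
#   "reactions": [{"id": str,
#                  "stoichiometry": {met_id: coeff},
#                  "lower_bound": float, "upper_bound": float,
#                  "genes": [str],              # may be empty, never omitted
#                  "gpr": str}],                # optional, default ""
#   "objective": str,
#   "exchanges": [str]
# }

def _model_to_json_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [{"id": m.id, "compartment": m.compartment}
                        for m in model.metabolites],
        "reactions": [{
            "id": r.id,
            "stoichiometry": dict(r.stoichiometry),
            "lower_bound": r.lower_bound,
            "upper_bound": r.upper_bound,
            "genes": sorted(r.genes),
            "gpr": r.gpr,
        } for r in model.reactions],
        "objective": model.objective,
        "exchanges": sorted(model.exchanges),
    }


def _model_from_json_dict(doc: dict) -> MetabolicModel:
    try:
        mets = [Metabolite(m["id"], m.get("compartment")) for m in doc["metabolites"]]
        rxns = [Reaction(r["id"], {k: float(v) for k, v in r["stoichiometry"].items()},
                         float(r["lower_bound"]), float(r["upper_bound"]),
                         frozenset(r["genes"]), r.get("gpr", ""))
                for r in doc["reactions"]]
        model = MetabolicModel(
            id=doc.get("id", "model"),
            metabolites=mets,
            reactions=rxns,
            objective=doc["objective"],
            exchanges=frozenset(doc.get("exchanges", [])),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"malformed JSON model: {exc!r}") from exc
    return model.validate()


# ---------------------------------------------------------------------------
# Tabular dialect (single TSV; one row per reaction)
# ---------------------------------------------------------------------------
#
# Columns: reaction_id, stoichiometry ("A:-1;B:1"), lower_bound, upper_bound,
#          genes ("g1;g2" or empty), objective (0/1), exchange (0/1),
#          compartments ("A:c;B:c", optional column).

def _model_from_tabular(path: Path) -> MetabolicModel:
    rxns: List[Reaction] = []
    objective = None
    exchanges = set()
    compartments: Dict[str, Optional[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "reaction_id" not in reader.fieldnames:
            raise ModelFormatError(f"{path}: missing tabular header with reaction_id")
        for row in reader:
            rid = row["reaction_id"].strip()
            try:
                stoich = {}
                for part in row["stoichiometry"].split(";"):
                    if not part.strip():
                        continue
                    mid, coeff = part.rsplit(":", 1)
                    stoich[mid.strip()] = float(coeff)
                lb, ub = float(row["lower_bound"]), float(row["upper_bound"])
            except (KeyError, ValueError) as exc:
                raise ModelFormatError(f"{path}: bad row for reaction {rid!r}: {exc}")
            genes = frozenset(g.strip() for g in row.get("genes", "").split(";")
                              if g.strip())
            rxns.append(Reaction(rid, stoich, lb, ub, genes))
            if row.get("objective", "0").strip() in ("1", "true", "True"):
                objective = rid
            if row.get("exchange", "0").strip() in ("1", "true", "True"):
                exchanges.add(rid)
            for part in (row.get("compartments") or "").split(";"):
                if part.strip():
                    mid, comp = part.rsplit(":", 1)
                    compartments[mid.strip()] = comp.strip()
    if objective is None:
        raise ModelInvalidError(f"{path}: no reaction flagged as objective")
    mids = sorted({m for r in rxns for m in r.stoichiometry})
    mets = [Metabolite(m, compartments.get(m)) for m in mids]
    model = MetabolicModel(id=path.stem, metabolites=mets, reactions=rxns,
                           objective=objective, exchanges=frozenset(exchanges))
    return model.validate()


def _model_to_tabular(model: MetabolicModel, path: Path) -> None:
    comp = {m.id: m.compartment for m in model.metabolites if m.compartment}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["reaction_id", "stoichiometry", "lower_bound", "upper_bound",
                    "genes", "objective", "exchange", "compartments"])
        for r in model.reactions:
            stoich = ";".join(f"{m}:{c:g}" for m, c in r.stoichiometry.items())
            comps = ";".join(f"{m}:{comp[m]}" for m in r.stoichiometry if m in comp)
            w.writerow([r.id, stoich, repr(r.lower_bound), repr(r.upper_bound),
                        ";".join(sorted(r.genes)),
                        int(r.id == model.objective),
                        int(r.id in model.exchanges), comps])


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC dialect (via cobrapy)
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    """Convert to a :class:`cobra.Model` (used for SBML I/O and as LP oracle)."""
    import cobra

    cm = cobra.Model(model.id)
    comp_ids = {m.compartment for m in model.metabolites if m.compartment}
    cm.compartments = {c: c for c in comp_ids}
    mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment or "c")
            for m in model.metabolites}
    cm.add_metabolites(list(mets.values()))
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cm.add_reactions([cr])
        cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        rule = r.gpr or " or ".join(sorted(r.genes))
        if rule:
            cr.gene_reaction_rule = rule
    cm.objective = model.objective
    return cm


def from_cobra(cm) -> MetabolicModel:
    """Convert a :class:`cobra.Model` to the package's representation."""
    mets = [Metabolite(m.id, m.compartment or None) for m in cm.metabolites]
    rxns = []
    for cr in cm.reactions:
        rxns.append(Reaction(
            cr.id,
            {m.id: float(c) for m, c in cr.metabolites.items()},
            float(cr.lower_bound), float(cr.upper_bound),
            frozenset(g.id for g in cr.genes),
            cr.gene_reaction_rule or "",
        ))
    objective = None
    for cr in cm.reactions:
        if cr.objective_coefficient:
            objective = cr.id
            break
    if objective is None:
        raise ModelInvalidError(f"SBML model {cm.id!r} declares no objective reaction")
    exchanges = frozenset(r.id for r in cm.exchanges) or frozenset(
        r.id for r in cm.reactions if len(r.metabolites) == 1)
    model = MetabolicModel(id=cm.id or "model", metabolites=mets, reactions=rxns,
                           objective=objective, exchanges=exchanges)
    return model.validate()


# ---------------------------------------------------------------------------
# read_model / write_model
# ---------------------------------------------------------------------------

DIALECTS = ("sbml-fbc", "json", "tabular")


def read_model(path, dialect: str = "json") -> MetabolicModel:
    """Read a metabolic model from ``path`` under the named dialect.

    Raises :class:`ModelFormatError` on parse failure and
    :class:`ModelInvalidError` on structural violations (lb > ub, missing
    objective, undeclared metabolites).
    """
    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"model file not found: {path}")
    if dialect == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"{path}: invalid JSON ({exc})") from exc
        return _model_from_json_dict(doc)
    if dialect == "tabular":
        return _model_from_tabular(path)
    if dialect == "sbml-fbc":
        import cobra.io
        try:
            cm = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # libsbml raises a zoo of types
            raise ModelFormatError(f"{path}: SBML parse failure ({exc})") from exc
        return from_cobra(cm)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def write_model(model: MetabolicModel, path, dialect: str = "json") -> None:
    """Write ``model`` to ``path``; the JSON dialect round-trips losslessly."""
    model.validate()
    path = Path(path)
    if dialect == "json":
        path.write_text(json.dumps(_model_to_json_dict(model), indent=1))
    elif dialect == "tabular":
        _model_to_tabular(model, path)
    elif dialect == "sbml-fbc":
        import cobra.io
        cobra.io.write_sbml_model(to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


# ---------------------------------------------------------------------------
# split_reversible
# ---------------------------------------------------------------------------

FWD_SUFFIX = "_fwd"
BWD_SUFFIX = "_bwd"


def split_reversible(model: MetabolicModel) -> MetabolicModel:
    """Decompose every reversible reaction into forward and backward copies.

    A reaction with bounds ``[lb, ub]`` and ``lb < 0`` is replaced by a
    forward copy ``[max(0, lb), max(0, ub)]`` and a backward copy with
    negated stoichiometry and bounds ``[max(0, -ub), -lb]``.  Irreversible
    reactions pass through unchanged.  The mapping original id ->
    (forward id, backward id) is stored on ``split_map``; the operation is
    idempotent on already-split models.
    """
    out_rxns: List[Reaction] = []
    split_map: Dict[str, Tuple[str, Optional[str]]] = {}
    exchanges = set()
    for r in model.reactions:
        if not r.reversible:
            out_rxns.append(r.copy())
            split_map[r.id] = (r.id, None)
            if r.id in model.exchanges:
                exchanges.add(r.id)
            continue
        fid, bid = r.id + FWD_SUFFIX, r.id + BWD_SUFFIX
        fwd = Reaction(fid, dict(r.stoichiometry),
                       max(0.0, r.lower_bound), max(0.0, r.upper_bound),
                       frozenset(r.genes), r.gpr)
        bwd = Reaction(bid, {m: -c for m, c in r.stoichiometry.items()},
                       max(0.0, -r.upper_bound), -r.lower_bound,
                       frozenset(r.genes), r.gpr)
        out_rxns.extend([fwd, bwd])
        split_map[r.id] = (fid, bid)
        if r.id in model.exchanges:
            exchanges.update([fid, bid])
    objective = split_map[model.objective][0]
    m = MetabolicModel(id=model.id, metabolites=list(model.metabolites),
                       reactions=out_rxns, objective=objective,
                       exchanges=frozenset(exchanges), split_map=split_map)
    return m.validate()


# ---------------------------------------------------------------------------
# reaction expression
# ---------------------------------------------------------------------------

def reaction_expression(model: MetabolicModel, expr: pd.DataFrame,
                        ) -> Tuple[pd.DataFrame, List[str]]:
    """Map gene expression onto reactions as the mean over each gene set.

    Parameters
    ----------
    expr : DataFrame, genes x samples.

    Returns
    -------
    (DataFrame reactions x samples, list of unmapped reaction ids).
    Reactions whose gene set is empty or entirely absent from ``expr`` are
    excluded from the matrix and listed in the flag report (never
    zero-filled).  Both split directions of a reversible reaction share the
    gene set and therefore receive the same expression row.

    Raises :class:`EmptyMappingError` when no model gene overlaps ``expr``.
    """
    validate_expression(expr)
    if not (set(model.genes) & set(expr.index)):
        raise EmptyMappingError(
            "no gene of the model appears in the expression matrix")
    rows, ids, unmapped = [], [], []
    for r in model.reactions:
        present = sorted(g for g in r.genes if g in expr.index)
        if not present:
            unmapped.append(r.id)
            continue
        rows.append(expr.loc[present].mean(axis=0))
        ids.append(r.id)
    return pd.DataFrame(rows, index=ids), unmapped


# ---------------------------------------------------------------------------
# media
# ---------------------------------------------------------------------------

def apply_media(model: MetabolicModel, media: Mapping[str, Tuple[float, float]],
                policy: str = "strict") -> MetabolicModel:
    """Replace exchange bounds from a media table.

    Under ``strict`` policy every exchange *not* listed has its uptake
    closed (lb = 0); under ``overlay`` unlisted exchanges are untouched.
    Media ids that are not exchange reactions raise :class:`MediaError`.
    """
    if policy not in ("strict", "overlay"):
        raise ValueError(f"unknown media policy {policy!r}")
    for rid in media:
        if rid not in model.exchanges:
            raise MediaError(f"media entry {rid!r} is not an exchange reaction")
    out = model.copy()
    for r in out.reactions:
        if r.id in media:
            lb, ub = media[r.id]
            r.lower_bound, r.upper_bound = float(lb), float(ub)
        elif policy == "strict" and r.id in out.exchanges:
            r.lower_bound = max(r.lower_bound, 0.0)
    return out.validate()


# ---------------------------------------------------------------------------
# expression / phenotype / media tables
# ---------------------------------------------------------------------------

def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    if expr.index.has_duplicates:
        raise ModelFormatError("expression matrix has duplicate gene rows; "
                               "aggregate first (see read_expression)")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ModelFormatError("expression matrix contains non-finite values")
    return expr


def read_expression(path, sep: str = "\t", strict_duplicates: bool = False,
                    ) -> pd.DataFrame:
    """Read a genes x samples expression table (gene ids in the first column).

    Duplicate gene rows are mean-aggregated with a warning by default;
    ``strict_duplicates=True`` turns them into an error.
    """
    expr = pd.read_csv(path, sep=sep, index_col=0)
    if expr.index.has_duplicates:
        if strict_duplicates:
            dups = expr.index[expr.index.duplicated()].unique().tolist()
            raise ModelFormatError(f"duplicate gene rows: {dups}")
        warnings.warn("duplicate gene rows mean-aggregated", stacklevel=2)
        expr = expr.groupby(level=0).mean()
    return validate_expression(expr.astype(float))


def read_phenotype(path, sep: str = "\t") -> pd.Series:
    """Read a (sample, value) phenotype table into a Series indexed by sample."""
    tab = pd.read_csv(path, sep=sep, index_col=0)
    s = tab.iloc[:, 0].astype(float)
    if s.index.has_duplicates:
        raise ModelFormatError("duplicate sample ids in phenotype table")
    if not np.isfinite(s.to_numpy()).all():
        raise ModelFormatError("phenotype contains non-finite values")
    return s


def align_phenotype(expr: pd.DataFrame, phenotype: pd.Series) -> pd.Series:
    """Check the phenotype covers exactly the expression samples; reorder."""
    if set(phenotype.index) != set(expr.columns):
        raise ModelFormatError(
            "phenotype samples do not match expression samples exactly")
    return phenotype.loc[list(expr.columns)]


def read_media(path, sep: str = "\t") -> Dict[str, Tuple[float, float]]:
    """Read a (reaction, lb, ub) media table."""
    tab = pd.read_csv(path, sep=sep)
    cols = [c.lower() for c in tab.columns]
    tab.columns = cols
    try:
        return {str(row["reaction"]): (float(row["lb"]), float(row["ub"]))
                for _, row in tab.iterrows()}
    except KeyError as exc:
        raise ModelFormatError(f"media table needs columns reaction/lb/ub: {exc}")
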