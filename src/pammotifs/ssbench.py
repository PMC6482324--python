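"""Benchmarking cluster assignments against secondary-structure labels.

Eight-state alphabet: B (isolated beta-bridge), E (extended strand),
G (3_10 helix), H (alpha helix), I (pi helix), T (turn), S (bend,
DSSP only), C (loop/irregular); X marks residues with no assignment.

The joint table P(A, y) accumulates, for every residue with label y,
the soft cluster probability of its feature vector under the mixture
(posterior responsibilities, no background).  Conditionals P(y|A) map
each cluster to its best label; clusters group into strand {B, E},
helix {G, H, I} and coil {C, S, T} for the three-state Q3 score, while
Q8 scores the best single label per cluster.  X-labelled residues are
excluded before normalisation in both scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pamm import ClusterModel, FeatureMatrix
from .structures import ResidueKey

logger = logging.getLogger(__name__)

SS_CODES = ("B", "E", "G", "H", "I", "T", "S", "C", "X")

SS3_GROUPS = {
    "strand": ("B", "E"),
    "helix": ("G", "H", "I"),
    "coil": ("C", "S", "T"),
}

_CODE_TO_GROUP = {code: g for g, codes in SS3_GROUPS.items() for code in codes}


@dataclass
class JointTable:
    """P(A, y) over clusters A (rows) and label codes y (columns)."""

    table: pd.DataFrame
    n_residues: int

    def marginal_clusters(self) -> pd.Series:
        return self.table.sum(axis=1)

    def marginal_labels(self) -> pd.Series:
        return self.table.sum(axis=0)

    def conditional_label_given_cluster(self) -> pd.DataFrame:
        """P(y | A): rows normalised."""
        return self.table.div(self.table.sum(axis=1), axis=0)

    def conditional_cluster_given_label(self) -> pd.DataFrame:
        """P(A | y): columns normalised."""
        return self.table.div(self.table.sum(axis=0), axis=1)

    def without_x(self) -> "JointTable":
        """Drop the X column and renormalise to unit total."""
        if "X" not in self.table.columns:
            return self
        sub = self.table.drop(columns="X")
        total = float(sub.to_numpy().sum())
        if total <= 0:
            raise ValueError("no labelled residues outside X")
        return JointTable(table=sub / total, n_residues=self.n_residues)


@dataclass
class ClassMapping:
    """Partition of cluster indices into strand / helix / coil sets."""

    strand: frozenset[int]
    helix: frozenset[int]
    coil: frozenset[int]


def joint_probability(
    features: FeatureMatrix | np.ndarray,
    labels: list[str] | np.ndarray,
    model: ClusterModel,
    hard: bool = False,
) -> JointTable:
    """Accumulate P(A, y) from per-sample soft cluster probabilities.

    With ``hard=True`` each sample contributes 1 to its argmax cluster
    instead of its posterior weights.
    """
    X = features.vectors if isinstance(features, FeatureMatrix) else np.asarray(features)
    labels = np.asarray(labels, dtype=object)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("one label per feature row required")
    bad = sorted(set(labels) - set(SS_CODES))
    if bad:
        raise ValueError(f"label code(s) outside the alphabet: {bad}")
    resp = model.responsibilities(X, zeta=0.0)  # (k, n)
    if hard:
        hard_resp = np.zeros_like(resp)
        hard_resp[resp.argmax(axis=0), np.arange(resp.shape[1])] = 1.0
        resp = hard_resp
    present = [c for c in SS_CODES if c in set(labels)]
    n = X.shape[0]
    data = {}
    for code in present:
        mask = labels == code
        data[code] = resp[:, mask].sum(axis=1) / n
    table = pd.DataFrame(data, index=range(model.n_modes))
    return JointTable(table=table, n_residues=n)


def map_clusters(table: JointTable) -> ClassMapping:
    """Assign each cluster to the 3-state group of its argmax P(y|A).

    X never wins the argmax; exact ties go conservatively to coil
    (logged).
    """
    cond = table.conditional_label_given_cluster()
    cond = cond.drop(columns=[c for c in ("X",) if c in cond.columns])
    strand, helix, coil = set(), set(), set()
    for cluster, row in cond.iterrows():
        best = row.max()
        winners = {_CODE_TO_GROUP[c] for c in row.index[np.isclose(row, best)]}
        if len(winners) > 1:
            logger.info("cluster %s label tie %s; assigning to coil", cluster, winners)
            group = "coil"
        else:
            group = winners.pop()
        {"strand": strand, "helix": helix, "coil": coil}[group].add(int(cluster))
    return ClassMapping(
        strand=frozenset(strand), helix=frozenset(helix), coil=frozenset(coil)
    )


def q3_score(table: JointTable, mapping: ClassMapping) -> float:
    """Three-state accuracy Q_E + Q_H + Q_C of the grouped mapping."""
    clusters = set(table.table.index)
    union = mapping.strand | mapping.helix | mapping.coil
    if union != clusters or len(mapping.strand) + len(mapping.helix) + len(
        mapping.coil
    ) != len(union):
        raise ValueError("mapping must partition the cluster indices")
    t = table.without_x().table
    score = 0.0
    for cluster_set, codes in (
        (mapping.strand, SS3_GROUPS["strand"]),
        (mapping.helix, SS3_GROUPS["helix"]),
        (mapping.coil, SS3_GROUPS["coil"]),
    ):
        cols = [c for c in codes if c in t.columns]
        rows = [c for c in cluster_set if c in t.index]
        if cols and rows:
            score += float(t.loc[rows, cols].to_numpy().sum())
    return score


def q8_score(table: JointTable, assignment: dict[int, str] | None = None) -> float:
    """Eight-state accuracy: sum over clusters of P(A, assigned label).

    Default assignment is each cluster's argmax-P(y|A) label (X
    excluded), which is the best achievable single-label choice.
    """
    t = table.without_x().table
    if assignment is None:
        assignment = {int(c): str(t.loc[c].idxmax()) for c in t.index}
    score = 0.0
    for cluster, code in assignment.items():
        if code == "X":
            raise ValueError("clusters cannot be assigned the X pseudo-label")
        if cluster in t.index and code in t.columns:
            score += float(t.loc[cluster, code])
    return score


# ---------------------------------------------------------------------------
# label readers


def _parse_dssp_output(lines: list[str]) -> dict[ResidueKey, str]:
    out: dict[ResidueKey, str] = {}
    in_body = False
    for line in lines:
        if not in_body:
            if line.lstrip().startswith("#  RESIDUE"):
                in_body = True
            continue
        if len(line) < 17:
            continue
        resnum_field = line[5:10].strip()
        if not resnum_field:  # chain-break record ('!')
            continue
        chain = line[11].strip()
        icode = line[10].strip()
        code = line[16].strip()
        out[(chain, int(resnum_field), icode)] = code if code else "X"
    if not in_body:
        raise ValueError("not a DSSP output file (no '#  RESIDUE' header)")
    return out


_STRIDE_CODES = {"H", "G", "I", "E", "B", "T", "C"}


def _parse_stride_output(lines: list[str]) -> dict[ResidueKey, str]:
    out: dict[ResidueKey, str] = {}
    for line in lines:
        if not line.startswith("ASG"):
            continue
        parts = line.split()
        # ASG resname chain resnum ordinal code name phi psi area
        chain = parts[2]
        resnum = int(parts[3])
        code = parts[5].upper()
        if code == "B":
            pass
        elif code not in _STRIDE_CODES:
            raise ValueError(f"unknown STRIDE code {parts[5]!r}")
        out[(chain, resnum, "")] = code
    if not out:
        raise ValueError("no ASG records found in STRIDE output")
    return out


def _parse_tsv(lines: list[str]) -> dict[ResidueKey, str]:
    out: dict[ResidueKey, str] = {}
    for i, line in enumerate(lines):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] in ("chain", "structure_id"):  # header
            continue
        if len(parts) == 3:
            chain, resnum, code = parts
        elif len(parts) == 4:
            _, chain, resnum, code = parts
        else:
            raise ValueError(f"line {i + 1}: expected 3 or 4 tab-separated fields")
        code = code.strip() or "X"
        if code not in SS_CODES:
            raise ValueError(f"line {i + 1}: unknown code {code!r}")
        out[(chain, int(resnum), "")] = code
    return out


def read_ss_labels(path: str | Path, dialect: str = "tsv") -> dict[ResidueKey, str]:
    """Read per-residue labels from DSSP output, STRIDE output or TSV.

    Returns a residue-key -> code map; blank assignments become X.
    STRIDE never emits S (bend is DSSP-specific).
    """
    lines = Path(path).read_text().splitlines()
    parsers = {
        "dssp_output": _parse_dssp_output,
        "stride_output": _parse_stride_output,
        "tsv": _parse_tsv,
    }
    if dialect not in parsers:
        raise ValueError(f"unknown dialect {dialect!r}")
    labels = parsers[dialect](lines)
    for key, code in labels.items():
        if code not in SS_CODES:
            raise ValueError(f"residue {key}: unknown code {code!r}")
    return labels


def labels_for_residues(
    residue_keys: list[ResidueKey], labels: dict[ResidueKey, str]
) -> list[str]:
    """Label per residue key; residues missing from the map get X (warned)."""
    out = []
    missing = 0
    for key in residue_keys:
        code = labels.get(key)
        if code is None:
            missing += 1
            code = "X"
        out.append(code)
    if missing:
        logger.warning("%d residue(s) missing from the label map; marked X", missing)
    return out
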