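"""Evaluation protocol: ranking metrics, PPVn with proteome decoys, and
the neoantigen binding-core scan.

PPVn follows the hit-vs-98-decoy design: every positive is accompanied
by length-matched random proteome decoys, predictions are ranked, and
the top n-percent of the ranked set is inspected.  Two readings are
implemented: ``precision`` (fraction of the top-k that are true
binders; the default, the only reading under which performance can
drop as the fraction grows) and ``recall`` (fraction of all binders
recovered in the top-k).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (roc_auc_score, average_precision_score,
                             f1_score, balanced_accuracy_score)

from .io import AA_SET, Dataset, PeptideRecord, allele_locus

DEFAULT_DECOYS_PER_HIT = 98
THRESHOLD = 0.5


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def auc(scores, labels) -> float:
    """ROC AUC (Mann-Whitney with tie correction)."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def aupr(scores, labels) -> float:
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(average_precision_score(labels, scores))


def f1(scores, labels, threshold: float = THRESHOLD) -> float:
    return float(f1_score(np.asarray(labels),
                          np.asarray(scores) >= threshold))


def balanced_acc(scores, labels, threshold: float = THRESHOLD) -> float:
    return float(balanced_accuracy_score(np.asarray(labels),
                                         np.asarray(scores) >= threshold))


def ppvn(scores, labels, fraction: float,
         variant: str = "precision") -> float:
    """Positive predictive value over the top n-percent of the ranking.

    k = ceil(fraction * n); ties are broken by stable record order.
    ``precision``: true binders among the top-k divided by k.
    ``recall``: true binders among the top-k divided by all binders.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if variant not in ("precision", "recall"):
        raise ValueError(f"unknown variant {variant!r}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n = len(scores)
    k = math.ceil(fraction * n)
    top = np.argsort(-scores, kind="stable")[:k]
    hits_in_top = int(labels[top].sum())
    if variant == "precision":
        return hits_in_top / k
    n_binders = int(labels.sum())
    return hits_in_top / n_binders if n_binders else 0.0


def make_decoys(hits: Dataset, proteome: dict[str, str],
                per_hit: int = DEFAULT_DECOYS_PER_HIT,
                seed: int = 0) -> Dataset:
    """Length-matched random proteome decoys, ``per_hit`` per positive.

    Decoys are uniform random substrings of the proteome with the same
    length as their hit, never equal to any sequence in the hit set,
    and never containing non-standard residues.  Deterministic per
    seed.
    """
    if not proteome:
        raise ValueError("proteome is empty")
    rng = np.random.default_rng(seed)
    names = sorted(proteome)
    seqs = [proteome[n] for n in names]
    hit_set = {r.peptide for r in hits.records}
    decoys: list[PeptideRecord] = []
    for rec in hits.records:
        L = len(rec.peptide)
        candidates = [s for s in seqs if len(s) >= L]
        if not candidates:
            raise ValueError(f"proteome has no sequence of length >= {L}")
        made = 0
        attempts = 0
        max_attempts = 1000 * per_hit
        while made < per_hit:
            if attempts > max_attempts:
                raise ValueError(
                    f"cannot draw {per_hit} decoys of length {L}")
            attempts += 1
            s = candidates[rng.integers(len(candidates))]
            pos = int(rng.integers(len(s) - L + 1))
            sub = s[pos:pos + L]
            if sub in hit_set or set(sub) - AA_SET:
                continue
            decoys.append(PeptideRecord(
                peptide=sub, allele=rec.allele, label=0,
                gene=rec.gene, domain=rec.domain, source="decoy"))
            made += 1
    return Dataset(decoys, alleles=hits.alleles)


def core_scan(oligomer: str, scorer, core_len: int = 9
              ) -> tuple[int, str, float, np.ndarray]:
    """Score every 9-mer window of an oligomer; return the best core.

    ``scorer`` maps a core string to a number.  Returns (offset, core,
    score, all_scores); ties resolve to the smallest offset.
    """
    if len(oligomer) < core_len:
        raise ValueError(
            f"oligomer length {len(oligomer)} < core length {core_len}")
    windows = [oligomer[o:o + core_len]
               for o in range(len(oligomer) - core_len + 1)]
    scores = np.array([float(scorer(w)) for w in windows])
    best = int(np.argmax(scores))   # argmax takes the first maximum
    return best, windows[best], float(scores[best]), scores


@dataclass
class EvaluationReport:
    """Metrics overall plus optional locus / length strata."""

    auc: float
    aupr: float
    f1: float
    balanced_acc: float
    ppvn: dict[str, float] = field(default_factory=dict)
    strata: pd.DataFrame | None = None
    ppvn_variant: str = "precision"

    def to_json(self, path=None) -> str:
        payload = {
            "auc": self.auc, "aupr": self.aupr, "f1": self.f1,
            "balanced_acc": self.balanced_acc,
            "ppvn_variant": self.ppvn_variant,
            "ppvn": self.ppvn,
        }
        if self.strata is not None:
            payload["strata"] = json.loads(
                self.strata.to_json(orient="records"))
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _safe_metrics(scores, labels) -> dict[str, float]:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return {k: float("nan")
                for k in ("auc", "aupr", "f1", "balanced_acc")}
    return {"auc": auc(scores, labels), "aupr": aupr(scores, labels),
            "f1": f1(scores, labels),
            "balanced_acc": balanced_acc(scores, labels)}


def stratified_report(scores, labels, meta: pd.DataFrame | None = None,
                      ppvn_fractions: tuple[float, ...] = (0.02, 0.40),
                      ppvn_variant: str = "precision") -> EvaluationReport:
    """Overall metrics plus per-locus and per-length strata.

    ``meta`` may carry ``allele`` and/or ``peptide`` columns; loci are
    grouped as DR vs. DQ&DP (the pan stratum is the overall row).
    Strata with a single class report NaN metrics, never zero; empty
    strata are omitted.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    overall = _safe_metrics(scores, labels)
    report = EvaluationReport(
        **overall,
        ppvn={f"ppvn_{int(f * 100)}pct": ppvn(scores, labels, f,
                                              ppvn_variant)
              for f in ppvn_fractions},
        ppvn_variant=ppvn_variant)
    if meta is None:
        return report
    rows = []
    if "allele" in meta.columns:
        locus = meta["allele"].map(
            lambda a: "DR" if allele_locus(a) == "DR" else "DQ&DP")
        for name, mask in [("DR", locus == "DR"),
                           ("DQ&DP", locus == "DQ&DP")]:
            if mask.sum() == 0:
                continue
            m = _safe_metrics(scores[mask.values], labels[mask.values])
            rows.append({"stratum": f"locus:{name}",
                         "n": int(mask.sum()), **m})
    if "peptide" in meta.columns:
        lengths = meta["peptide"].str.len()
        for L in sorted(lengths.unique()):
            mask = (lengths == L).values
            m = _safe_metrics(scores[mask], labels[mask])
            rows.append({"stratum": f"length:{L}",
                         "n": int(mask.sum()), **m})
    report.strata = pd.DataFrame(rows) if rows else None
    return report
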