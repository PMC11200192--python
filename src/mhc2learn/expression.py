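"""Gene-expression feature transform.

Source-gene abundance (TPM) contributes to the presentation score: a
peptide from a highly expressed gene is more likely to be sampled by the
class II processing pathway.  The transform used downstream is
``log10(X + 10^6)`` of the TPM value X; for vaccine-candidate scoring a
fixed TPM of 50 models the high local density of vaccinated peptide.
"""

from __future__ import annotations

import math

VACCINE_TPM = 50.0


def expression_feature(gene: str, table: dict[str, float],
                       tpm_override: float | None = None,
                       formula: str = "offset1e6") -> float | None:
    """Transformed expression value for a gene, or None (exclusion).

    Looks the gene up in the TPM table unless ``tpm_override`` is given
    (vaccine-candidate mode uses 50).  Genes absent from the table with
    no override return ``None`` — the record is to be excluded from
    analysis.  ``formula`` selects ``log10(X + 10^6)`` (default) or the
    conventional ``log10(X + 1)`` (non-default alternative; changes the
    output scale).
    """
    if tpm_override is not None:
        x = float(tpm_override)
    elif gene in table:
        x = float(table[gene])
    else:
        return None
    if x < 0:
        raise ValueError(f"negative TPM {x} for gene {gene!r}")
    if formula == "offset1e6":
        return math.log10(x + 1e6)
    if formula == "offset1":
        return math.log10(x + 1.0)
    raise ValueError(f"unknown formula {formula!r}")


def expression_score(gene: str, table: dict[str, float],
                     tpm_override: float | None = None,
                     half_tpm: float = VACCINE_TPM) -> float | None:
    """Saturating [0, 1] expression branch score for fusion.

    ``X / (X + half_tpm)`` of the TPM value: 0 at zero expression, 0.5
    at the vaccine reference of 50 TPM, approaching 1 for abundant
    transcripts.  Returns None when the gene is excluded.
    """
    if tpm_override is not None:
        x = float(tpm_override)
    elif gene in table:
        x = float(table[gene])
    else:
        return None
    if x < 0:
        raise ValueError(f"negative TPM {x} for gene {gene!r}")
    return x / (x + half_tpm)
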