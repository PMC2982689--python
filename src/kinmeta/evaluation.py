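"""Benchmark evaluation: confirmed edges against a curated gold standard.

A predicted edge is *confirmed* when the identical directed (TF, target)
pair appears in the gold-standard set — exact, case-sensitive id matching,
no fuzzy mapping.  The confirmed-edge ratio divides by the predicted
network's size only; gold pairs whose genes never entered the expression
matrix still count as unconfirmed opportunities, which keeps ratios
comparable across methods run on the same benchmark.
"""

from __future__ import annotations

from .io import GoldStandard, Network, ValidationError


def confirmed_edges(network: Network, gold: GoldStandard) -> int:
    """Number of predicted directed edges present in the gold standard."""
    if len(network) == 0:
        raise ValidationError("cannot evaluate an empty network")
    return len(network.pair_set & gold.pairs)


def confirmed_ratio(network: Network, gold: GoldStandard) -> float:
    """Confirmed edges divided by total predicted edges."""
    return confirmed_edges(network, gold) / len(network)


def precision_recall(network: Network, gold: GoldStandard) -> tuple[float, float]:
    """(precision, recall) of the predicted edge set against the gold pairs.

    Precision is the confirmed ratio; recall divides by the gold-standard
    size.  Mainly used against planted synthetic regulons, where the gold
    set is the complete truth.
    """
    c = confirmed_edges(network, gold)
    return c / len(network), c / len(gold)
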