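"""XCI skew from methylation-sensitive restriction (HpaII) peak heights.

HpaII cuts unmethylated sites, destroying the allele residing on the
active X before PCR; the surviving peak of each allele is therefore
proportional to the fraction of cells in which that allele's chromosome
is inactive. Dividing each digested height by its undigested height
first corrects allele-specific amplification bias, and the larger
normalized share, in percent, is the XCI ratio: 50 is perfectly random
inactivation, 100 completely skewed.
"""

from __future__ import annotations

from .model import PeakPair, XciResult

DEFAULT_SKEW_THRESHOLD = 80.0


def xci_ratio(peaks: PeakPair, skew_threshold: float = DEFAULT_SKEW_THRESHOLD) -> XciResult:
    """Compute the XCI ratio and classify skew.

    A single-peak (homozygous) sample is uninformative. Otherwise, with
    digested/undigested heights (d_i, u_i), the per-allele survival is
    r_i = d_i / u_i and the ratio is 100·max(r_i) / (r_1 + r_2),
    classified skewed when ≥ ``skew_threshold`` (default 80) and random
    below it. Complete digestion of both alleles (r_1 + r_2 = 0) is
    degenerate and reported not applicable.
    """
    if peaks.n_alleles == 1:
        return XciResult(ratio=None, classification="uninformative")
    r = [d / u for d, u in zip(peaks.digested, peaks.undigested)]
    total = sum(r)
    if total == 0:
        return XciResult(ratio=None, classification="not_applicable")
    ratio = 100.0 * max(r) / total
    return XciResult(
        ratio=ratio,
        classification="skewed" if ratio >= skew_threshold else "random",
    )
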