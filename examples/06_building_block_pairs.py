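"""Does building-block solubility predict the degrader's solubility?

For pairs of degraders differing in a single moiety, the pair report
compares the log S ordering of the two molecules with the ordering of the
swapped building blocks: concordant when they match, discordant when they
invert (e.g. when ionisable blocks lose their charge inside the
conjugate), indeterminate when a block value is censored or missing."""

from protacsol.datasets import BENCHMARK_PAIRS, BUILDING_BLOCK_LOG_S, protac_log_s
from protacsol.models import compare_pair

log_s = protac_log_s()
for a, b, moiety, block_a, block_b in BENCHMARK_PAIRS:
    rep = compare_pair(
        (a, log_s[a]), (b, log_s[b]), moiety,
        (block_a, BUILDING_BLOCK_LOG_S[block_a]) if block_a else None,
        (block_b, BUILDING_BLOCK_LOG_S[block_b]) if block_b else None)
    delta = f"{rep.delta_log_s:+.2f}" if rep.delta_log_s is not None else "  n/a"
    print(f"{a:8s} vs {b:9s} ({moiety.value:9s}): delta log S = {delta}  -> {rep.concordance}")
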