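"""Test each language's loading direction with a mixed-model LRT.

Generates the six-language reference suite (three back-loaded, three
front-loaded at a 0.5-bit contrast) and, per language, compares a
null mixed model (surprisal ~ words + dyad/speaker intercepts)
against one adding utterance half, at the Bonferroni-corrected
α = 0.008. A positive half estimate classifies the language as
back-loaded, a negative one as front-loaded.
"""

import pandas as pd

from infodist import inference, make_fixture
from infodist.calibration import loading_table_for

suite = make_fixture("reference", seed=3)
for corpus, truth in suite:
    table = loading_table_for(corpus)
    long = inference.half_long_table(table)
    res = inference.lrt_half_effect(long)
    est = inference.half_effect_estimate(res)
    verdict = "back-loaded" if est > 0 else "front-loaded"
    star = "significant" if res.significant else "n.s."
    print(
        f"{corpus.language_label:8s} (true: {truth.config.loading_mode:5s})  "
        f"χ²(1) = {res.chisq:7.2f}, p = {res.p_value:.2e}, "
        f"estimate = {est:+.3f} bits → {verdict} [{star} at α = {res.alpha_used}]"
    )
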