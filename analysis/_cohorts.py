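"""Shared definition of the demonstration screen used by the numbered
analysis scripts: 20 synthetic gut-microbiota-style taxa against one binary
outcome — 8 planted causal (theta = 0.2), one with planted heterogeneity,
one with planted directional pleiotropy, 10 clean nulls."""

from mrscreen.simulate import SimulationTruth

SEED = 1
LARGE_N = dict(n_exp=200_000, n_out=200_000)

LEVELS = ("phylum", "class", "order", "family", "genus")


def demo_truths() -> dict[str, SimulationTruth]:
    truths: dict[str, SimulationTruth] = {}
    for i in range(20):
        level = LEVELS[i % len(LEVELS)]
        name = f"{level}.Taxon{i:02d}"
        kw: dict = dict(seed=SEED * 1000 + i, k_true=10, **LARGE_N)
        if i < 8:
            kw["theta"] = 0.2
        elif i == 8:
            kw.update(theta=0.2, het_sd=0.05)
        elif i == 9:
            kw.update(theta=0.2, pleiotropy_mode="directional",
                      pleio_mean=0.1, pleio_sd=0.02)
        truths[name] = SimulationTruth(**kw)
    return truths


def causal_ids() -> set[str]:
    return {name for i, name in enumerate(demo_truths()) if i < 8}


def violation_ids() -> set[str]:
    return {name for i, name in enumerate(demo_truths()) if i in (8, 9)}
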