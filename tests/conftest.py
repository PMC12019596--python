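import pytest

from thermotrans import (
    TrainingConfig,
    TranslationRule,
    generate_rule_pairs,
    train_tiny_translator,
)

RULE = TranslationRule(substitution_map={"G": "A", "S": "T"}, name="GA-ST")


@pytest.fixture(scope="session")
def ga_st_rule():
    return RULE


@pytest.fixture(scope="session")
def trained_rule_model():
    """Tiny translator trained once on 500 {G→A, S→T} rule pairs."""
    pairs = generate_rule_pairs(500, seed=3, rule=RULE)
    cfg = TrainingConfig(max_learning_rate=0.05, max_epochs=30, seed=0)
    return train_tiny_translator(pairs, cfg)


@pytest.fixture(scope="session")
def held_out_rule_pairs():
    """Rule pairs generated under a seed disjoint from the training seed."""
    return generate_rule_pairs(50, seed=99, rule=RULE)
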