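import pytest
from hypothesis import settings

from surveyrules import Category, Codebook, Question

settings.register_profile("default", derandomize=True, max_examples=60)
settings.load_profile("default")


def contingency_transactions(n_neg_creative=150, n_neg_not=50, n_pos_creative=750, n_pos_not=50):
    """Feedback-type / creativity toy cohort as 1,000 market-basket transactions."""
    tx = []
    tx += [frozenset({"NegFB", "Creative"})] * n_neg_creative
    tx += [frozenset({"NegFB", "NotCreative"})] * n_neg_not
    tx += [frozenset({"PosFB", "Creative"})] * n_pos_creative
    tx += [frozenset({"PosFB", "NotCreative"})] * n_pos_not
    return tx


@pytest.fixture
def toy_transactions():
    return contingency_transactions()


@pytest.fixture
def small_codebook():
    """A miniature instrument with the demographic and Likert question styles."""
    return Codebook(
        [
            Question(
                number=2,
                text="Your gender",
                answer_labels=("Male", "Female", "Other"),
                answer_index_base=0,
                category=Category.DEMOGRAPHICS,
            ),
            Question(
                number=37,
                text="I am more likely than the average person to get COVID-19.",
                answer_labels=("Strongly Disagree", "Disagree", "Neutral", "Agree", "Strongly Agree"),
                answer_index_base=1,
                category=Category.PERCEIVED_SUSCEPTIBILITY_SEVERITY,
            ),
            Question(
                number=38,
                text="COVID-19 is a hopeless disease.",
                answer_labels=("Strongly Disagree", "Disagree", "Neutral", "Agree", "Strongly Agree"),
                answer_index_base=1,
                category=Category.PERCEIVED_SUSCEPTIBILITY_SEVERITY,
            ),
            Question(
                number=41,
                text="During the peak time, I kept my emotions to myself.",
                answer_labels=(
                    "Strongly Disagree",
                    "Disagree",
                    "Slightly Disagree",
                    "Neutral",
                    "Slightly Agree",
                    "Agree",
                    "Strongly Agree",
                ),
                answer_index_base=1,
                category=Category.PSYCHOLOGICAL_DISTRESS,
            ),
            Question(
                number=153,
                text="During the peak time, I felt worthless.",
                answer_labels=("Strongly Disagree", "Disagree", "Neutral", "Agree", "Strongly Agree"),
                answer_index_base=1,
                category=Category.PSYCHOLOGICAL_DISTRESS,
            ),
        ]
    )


def random_instance(rng, max_items=12, max_transactions=200):
    """A random small mining instance for oracle-equivalence checks."""
    n_items = int(rng.integers(2, max_items + 1))
    alphabet = [f"i{k}" for k in range(n_items)]
    n_tx = int(rng.integers(5, max_transactions + 1))
    transactions = []
    for _ in range(n_tx):
        size = int(rng.integers(0, min(6, n_items) + 1))
        transactions.append(frozenset(rng.choice(alphabet, size=size, replace=False)))
    minsup = float(rng.uniform(0.05, 0.8))
    max_len = None if rng.random() < 0.5 else int(rng.integers(1, 5))
    return transactions, minsup, max_len
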