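"""Encode survey answers as market-basket transactions.

Each question-answer pair becomes one item "<question>-<answer>", so a
participant's report is a basket of items — the representation every later
mining stage consumes.
"""

from surveyrules import (
    Category,
    Codebook,
    Question,
    SurveyReport,
    build_transactions,
    decode_item,
    encode_item,
)

codebook = Codebook(
    [
        Question(2, "Your gender", ("Male", "Female", "Other"), 0, Category.DEMOGRAPHICS),
        Question(
            37,
            "I am more likely than the average person to get COVID-19.",
            ("Strongly Disagree", "Disagree", "Neutral", "Agree", "Strongly Agree"),
            1,
            Category.PERCEIVED_SUSCEPTIBILITY_SEVERITY,
        ),
        Question(
            41,
            "During the peak time, I kept my emotions to myself.",
            ("Strongly Disagree", "Disagree", "Slightly Disagree", "Neutral",
             "Slightly Agree", "Agree", "Strongly Agree"),
            1,
            Category.PSYCHOLOGICAL_DISTRESS,
        ),
    ]
)

item = encode_item(37, 2, codebook)
print(f"question 37, answer 2 encodes to {item!r}")
print(f"{item!r} decodes back to {decode_item(item)}")

report = SurveyReport("p001", answers={2: 0, 37: 2, 41: 4}, group_label="male")
(transaction,) = build_transactions([report], codebook, include_group_item=True)
print(f"participant {report.participant_id} basket: {sorted(transaction.items)}")
# The basket {'2-0', '37-2', '41-4'} reads: male, disagrees they are more
# susceptible than average, slightly agrees they kept emotions to themselves.
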