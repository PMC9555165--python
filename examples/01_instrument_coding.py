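"""Instrument coding: products, ordinal categories, nominal combinations.

Builds a single respondent's answers and shows the three codings the package
uses: the traditional intensity x frequency product (0-81 total), the ordinal
7-level product category fed to the graded-response model, and the 10-level
nominal combination label fed to the nominal-response model.
"""

from irtscore import (
    ItemResponse,
    ResponseRecord,
    combination_category,
    frequency_sum_score,
    product_category,
    product_score,
    unweighted_sum_score,
)
from irtscore.instrument import ITEM_NAMES

# moderate depressed mood nearly every day, mild insomnia for several days,
# severe fatigue for more than a week; everything else absent
answers = {1: (2, 3), 3: (1, 1), 4: (3, 2)}
responses = tuple(
    ItemResponse(*answers.get(i, (0, 0))) for i in range(1, 10)
)
record = ResponseRecord(responses, gender="female")

print(f"{'item':<14}{'int':>4}{'freq':>5}{'product':>8}{'ordinal':>8}{'nominal':>8}")
for name, r in zip(ITEM_NAMES, record.responses):
    print(f"{name:<14}{r.intensity:>4}{r.frequency:>5}"
          f"{product_score(r):>8}{product_category(r):>8}{combination_category(r):>8}")

print(f"\nunweighted 9Q total (0-81): {unweighted_sum_score(record)}")
print(f"frequency sum (0-27):       {frequency_sum_score(record)}")
# The product column is what classical scoring adds up; the ordinal column
# relabels the 7 attainable products 0..6; the nominal column keeps (2,3)
# distinct from (3,2) so the NRM can weight them differently.
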