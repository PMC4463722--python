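"""Read-across arithmetic on the packaged worked-example category tables.

Each row of the packaged tables is one category: a query chemical's
experimental LOEL plus the LOELs of its three nearest analogs. The predicted
LOEL is the arithmetic mean of the analogs; the fold difference is the
larger/smaller ratio of experimental and predicted LOEL, and a fold below 10
counts as a prediction within one order of magnitude.
"""

from toxknn import assign_bin, fold_difference, load_fixture, predict_loel
from toxknn._rounding import round_half_up

train = load_fixture("table2")
row = train.iloc[0]
analogs = [float(row.analog1_loel), float(row.analog2_loel), float(row.analog3_loel)]
pred = predict_loel(analogs)
fold = fold_difference(row.query_loel, pred)
print(f"training category 1: analogs {analogs} mg/kg/day")
print(f"  predicted LOEL  = {round_half_up(pred, 2)} mg/kg/day (mean of analogs)")
print(f"  experimental    = {row.query_loel} mg/kg/day")
print(f"  fold difference = {round_half_up(fold, 2)} -> bin {assign_bin(fold)}")

for name, table_id in (("training", "table2"), ("test", "table3")):
    fix = load_fixture(table_id)
    folds = [
        fold_difference(r.query_loel, predict_loel([r.analog1_loel, r.analog2_loel, r.analog3_loel]))
        for r in fix.itertuples(index=False)
    ]
    lt10 = sum(f < 10 for f in folds)
    mid = sum(10 <= f <= 100 for f in folds)
    gt100 = sum(f > 100 for f in folds)
    print(f"{name} set ({len(folds)} queries): {lt10} within 10-fold, "
          f"{mid} within 10-100-fold, {gt100} beyond 100-fold")
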