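"""Score a set of per-plant silique counts against ground truth.

MAE and RMSE measure the size of the count errors; CA is the mean of the
per-plant predicted/actual ratios in percent, so 100% means counts match
on average.
"""
from kanglnet import counting_scores

pairs = [(78, 75), (144, 142), (293, 285), (228, 222), (232, 227)]
report = counting_scores(pairs)
print(f"plants: {len(pairs)}")
print(f"MAE  = {report.mae:.2f} siliques")
print(f"RMSE = {report.rmse:.2f} siliques")
print(f"CA   = {report.ca_percent:.2f}%")
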