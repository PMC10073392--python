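"""Score a single WPAI response set.

An employed respondent who missed 8 hours of work because of migraine,
worked 32 hours, rated their at-work impairment 6/10 and their non-work
activity impairment 7/10.
"""

from wpaimc import WpaiItems, score_wpai

items = WpaiItems(
    employed=True,
    hours_missed_migraine=8.0,
    hours_missed_other=0.0,
    hours_worked=32.0,
    presenteeism_degree=6,
    activity_degree=7,
)
scores = score_wpai(items)

print(f"absenteeism          {scores.absenteeism_pct:6.1f} %")
print(f"presenteeism         {scores.presenteeism_pct:6.1f} %")
print(f"overall work loss    {scores.overall_work_productivity_loss_pct:6.1f} %")
print(f"activity impairment  {scores.activity_impairment_pct:6.1f} %")
print()
print("Each score is the share of time (or capacity) lost in its domain;")
print("overall work loss combines absence with reduced on-the-job output.")
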