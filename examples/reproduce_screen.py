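"""Classify every deficiency of the bundled modifier screen.

Loads the packaged control series (16 experimental rounds) and the 24
modifier deficiencies, rebuilds the control band, and runs the
two-criterion classifier: outside the band AND significant against the
round's matched control.
"""

from ndjscreen import as_percent, datasets, screen_report

rows = datasets.screen_rows()
report = screen_report(rows)

print(
    f"control band: ({as_percent(report.band.band_low)}%, "
    f"{as_percent(report.band.band_high)}%) from {report.band.n} rounds"
)
print(report.to_frame().to_string(index=False))
summary = ", ".join(f"{v} {k}" for k, v in report.summary.items() if v)
print(f"\nsummary: {summary}")
print(
    "\nEach row shows the viability-corrected NDJ frequency, its difference to\n"
    "the matched control and to the control average (percentage points), the\n"
    "hierarchy-test p-value, and the resulting call."
)
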