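"""From raw retention times to BRlogD, log kw_IAM and Delta log kw_IAM.

An RP18 injection at 60% acetonitrile gives the lipophilicity index
BRlogD = 3.31*log k'60 + 2.79; IAM retention at 10-50% acetonitrile is
extrapolated linearly to 0% organic to give log kw_IAM; the polarity
descriptor Delta log kw_IAM is the excess of log kw_IAM over the PSA-zero
baseline 0.92*BRlogD - 1.03."""

from protacsol import (
    ColumnSystem,
    RetentionPoint,
    RetentionSeries,
    descriptors_from_series,
)

t0 = 1.1  # dead time, min
rp18 = RetentionSeries("DEG-X", ColumnSystem.RP18_ISOCRATIC_60ACN, [
    RetentionPoint(60.0, 3.95, t0, replicate=1),
    RetentionPoint(60.0, 3.99, t0, replicate=2),
])
t0_iam = 2.0
iam = RetentionSeries("DEG-X", ColumnSystem.IAM_GRADIENT_POINTS, [
    RetentionPoint(pct, t0_iam * (1 + 10 ** (2.4 - 0.045 * pct)), t0_iam)
    for pct in (10, 20, 30, 40, 50)
])

profile = descriptors_from_series([rp18, iam])["DEG-X"]
print(f"BRlogD           = {profile.brlogd:.2f}")
print(f"log kw_IAM       = {profile.log_kw_iam:.2f}  (extrapolation R2 = {profile.extrapolation_r2:.3f})")
print(f"clog kw_IAM      = {profile.clog_kw_iam:.2f}  (expected for a PSA-zero analyte)")
print(f"Delta log kw_IAM = {profile.delta_log_kw_iam:.2f}  (polarity excess)")
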