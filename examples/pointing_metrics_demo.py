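"""Score a wobbly reach against its task axis with the pointing metrics.

The task axis is the straight line from the start to the target.  ODC
counts reversals of progress along the axis (consistency toward the
target), MDC counts reversals across it (smoothness), ME is the mean
absolute perpendicular deviation and MV its standard deviation
(straightness).
"""

import numpy as np

from reachbench import pointing_metrics

start, target = np.array([0.0, 0.0]), np.array([10.0, 0.0])

straight = np.column_stack([np.linspace(0, 10, 20), np.zeros(20)])
wobbly = straight + np.column_stack(
    [np.zeros(20), 0.8 * np.sin(np.linspace(0, 3 * np.pi, 20))])
overshoot = np.column_stack(
    [np.concatenate([np.linspace(0, 12, 15), np.linspace(12, 10, 5)]),
     np.zeros(20)])

for name, path in [("straight", straight), ("wobbly", wobbly),
                   ("overshoot", overshoot)]:
    pm = pointing_metrics(path, start, target)
    print(f"{name:10s} ODC={pm.odc} MDC={pm.mdc} "
          f"ME={pm.me:.3f} MV={pm.mv:.3f}")

print("\nThe straight path scores zero everywhere; lateral wobble raises")
print("MDC/ME/MV but not ODC; overshooting and returning raises only ODC.")
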