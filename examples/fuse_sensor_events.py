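"""Fuse a stream of color-mark-sensor triggers into a label position.

Sensors 1/4, 2/5 and 3/6 sweep detection lines A, B and C.  The first
two triggers on *distinct* lines localize the label: the time gap,
scaled by the conveyor speed, fixes the intersection of the two lines.
"""

from cropsignal import SensorArray, SensorEvent, select_signal

array = SensorArray()  # 720x720 frame, center 360, 400 px/s conveyor

# Sensor 1 (line A) fires, its line-mate 4 confirms, then sensor 2
# (line B) fires 50 ms later.  (1, 4) share a line and cannot fuse;
# (1, 2) is the earliest valid pair.
events = [
    SensorEvent(sensor_id=1, timestamp=0.00),
    SensorEvent(sensor_id=4, timestamp=0.01),
    SensorEvent(sensor_id=2, timestamp=0.05),
]

signal = select_signal(events, array)
print(f"fused pair: sensors {signal.ser_1} -> {signal.ser_2}")
print(f"trigger gap: {signal.dt * 1000:.0f} ms "
      f"({signal.dt * array.speed_px_s:.0f} px of travel)")
print(f"estimated label position (x, y): {signal.point}")

# A then B lands on the main diagonal: 360 - 0.05 * 400 = 340 on both
# axes, so the label sits 20 px up-left of the image center.
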