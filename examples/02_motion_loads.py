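"""Build the four motion load magnitudes from body parameters.

The head weight is a fixed fraction (7.83%) of body weight; each motion's
torque is the isometric neck strength (N*mm per kg of head mass) times the
head mass.  These two numbers fully define the load cases the solver runs.
"""

from cervifem.loading import (BodyParams, IsometricStrengthTable,
                              head_weight_force, torque_table)

body = BodyParams(body_mass=39.97)          # kg
hw = head_weight_force(body)
print(f"head weight: {hw:.1f} N  (= {body.body_mass} kg x "
      f"{body.head_mass_fraction:.4f} x {body.g} m/s^2)")

table = IsometricStrengthTable()
for motion, torque in torque_table(body, table).items():
    print(f"{motion:<16} strength {table.strength(motion):>6.0f} N*mm/kg"
          f"  ->  torque {torque:>5d} N*mm")
print("\nThe gravity load is split over the two C2 facet patches; each "
      "torque drives one motion case about its anatomical axis.")
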