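{
 "links": [
  {
   "name": "front_torso",
   "parent": null,
   "length": 0.42,
   "mass": 9.0,
   "radius": 0.1,
   "offset": 0.0,
   "axis": [
    1.0,
    0.0,
    0.0
   ]
  },
  {
   "name": "rear_torso",
   "parent": "front_torso",
   "length": 0.38,
   "mass": 7.0,
   "radius": 0.1,
   "offset": [
    0.0,
    0.0,
    0.0
   ],
   "axis": [
    -1.0,
    0.0,
    0.0
   ]
  },
  {
   "name": "neck_head",
   "parent": "front_torso",
   "length": 0.32,
   "mass": 3.5,
   "radius": 0.05,
   "offset": 0.42,
   "axis": [
    1.0,
    0.0,
    0.0
   ]
  },
  {
   "name": "tail_base",
   "parent": "rear_torso",
   "length": 0.3,
   "mass": 0.6,
   "radius": 0.02,
   "offset": 0.38,
   "axis": [
    -1.0,
    0.0,
    0.0
   ]
  },
  {
   "name": "tail_tip",
   "parent": "tail_base",
   "length": 0.3,
   "mass": 0.4,
   "radius": 0.015,
   "offset": 0.3,
   "axis": [
    -1.0,
    0.0,
    0.0
   ]
  },
  {
   "name": "lf_upper",
   "parent": "front_torso",
   "length": 0.26,
   "mass": 1.6,
   "radius": 0.035,
   "offset": [
    0.38,
    0.09,
    -0.03
   ],
   "axis": [
    0.0,
    0.0,
    -1.0
   ]
  },
  {
   "name": "lf_lower",
   "parent": "lf_upper",
   "length": 0.24,
   "mass": 0.8,
   "radius": 0.025,
   "offset": 0.26,
   "axis": [
    0.0,
    0.0,
    -1.0
   ]
  },
  {
   "name": "lf_paw",
   "parent": "lf_lower",
   "length": 0.1,
   "mass": 0.25,
   "radius": 0.018,
   "offset": 0.24,
   "axis": [
    0.0,
    0.0,
    -1.0
   ]
  },
  {
   "name": "rf_upper",
   "parent": "front_torso",
   "length": 0.26,
   "mass": 1.6,
   "radius": 0.035,
   "offset": [
    0.38,
    -0.09,
    -0.03
   ],
   "axis": [
    0.0,
    0.0,
    -1.0
   ]
  },
  {
   "name": "rf_lower",
   "parent": "rf_upper",
   "length": 0.24,
   "mass": 0.8,
   "radius": 0.025,
   "offset": 0.26,
   "axis": [
    0.0,
    0.0,
    -1.0
   ]
  },
  {
   "name": "rf_paw",
   "parent": "rf_lower",
   "length": 0.1,
   "mass": 0.25,
   "radius": 0.018,
   "offset": 0.24,
   "axis": [
    0.0,
    0.0,
    -1.0
   ]
  },
  {
   "name": "lh_upper",
   "parent": "rear_torso",
   "length": 0.3,
   "mass": 2.2,
   "radius": 0.035,
   "offset": [
    0.34,
    0.09,
    -0.03
   ],
   "axis": [
    0.0,
    0.0,
    -1.0
   ]
  },
  {
   "name": "lh_lower",
   "parent": "lh_upper",
   "length": 0.28,
   "mass": 1.0,
   "radius": 0.025,
   "offset": 0.3,
   "axis": [
    0.0,
    0.0,
    -1.0
   ]
  },
  {
   "name": "lh_paw",
   "parent": "lh_lower",
   "length": 0.12,
   "mass": 0.3,
   "radius": 0.018,
   "offset": 0.28,
   "axis": [
    0.0,
    0.0,
    -1.0
   ]
  },
  {
   "name": "rh_upper",
   "parent": "rear_torso",
   "length": 0.3,
   "mass": 2.2,
   "radius": 0.035,
   "offset": [
    0.34,
    -0.09,
    -0.03
   ],
   "axis": [
    0.0,
    0.0,
    -1.0
   ]
  },
  {
   "name": "rh_lower",
   "parent": "rh_upper",
   "length": 0.28,
   "mass": 1.0,
   "radius": 0.025,
   "offset": 0.3,
   "axis": [
    0.0,
    0.0,
    -1.0
   ]
  },
  {
   "name": "rh_paw",
   "parent": "rh_lower",
   "length": 0.12,
   "mass": 0.3,
   "radius": 0.018,
   "offset": 0.28,
   "axis": [
    0.0,
    0.0,
    -1.0
   ]
  }
 ],
 "joints": [
  {
   "kind": "universal",
   "i": "front_torso",
   "j": "rear_torso"
  },
  {
   "kind": "spherical",
   "i": "front_torso",
   "j": "neck_head"
  },
  {
   "kind": "spherical",
   "i": "rear_torso",
   "j": "tail_base"
  },
  {
   "kind": "spherical",
   "i": "tail_base",
   "j": "tail_tip"
  },
  {
   "kind": "spherical",
   "i": "front_torso",
   "j": "lf_upper"
  },
  {
   "kind": "revolute",
   "i": "lf_upper",
   "j": "lf_lower"
  },
  {
   "kind": "revolute",
   "i": "lf_lower",
   "j": "lf_paw"
  },
  {
   "kind": "spherical",
   "i": "front_torso",
   "j": "rf_upper"
  },
  {
   "kind": "revolute",
   "i": "rf_upper",
   "j": "rf_lower"
  },
  {
   "kind": "revolute",
   "i": "rf_lower",
   "j": "rf_paw"
  },
  {
   "kind": "spherical",
   "i": "rear_torso",
   "j": "lh_upper"
  },
  {
   "kind": "revolute",
   "i": "lh_upper",
   "j": "lh_lower"
  },
  {
   "kind": "revolute",
   "i": "lh_lower",
   "j": "lh_paw"
  },
  {
   "kind": "spherical",
   "i": "rear_torso",
   "j": "rh_upper"
  },
  {
   "kind": "revolute",
   "i": "rh_upper",
   "j": "rh_lower"
  },
  {
   "kind": "revolute",
   "i": "rh_lower",
   "j": "rh_paw"
  }
 ],
 "markers": [
  {
   "name": "nose",
   "link": "neck_head",
   "offset_xyz": [
    0.32,
    0.0,
    0.02
   ]
  },
  {
   "name": "r_eye",
   "link": "neck_head",
   "offset_xyz": [
    0.27,
    -0.03,
    0.05
   ]
  },
  {
   "name": "l_eye",
   "link": "neck_head",
   "offset_xyz": [
    0.27,
    0.03,
    0.05
   ]
  },
  {
   "name": "neck_base",
   "link": "front_torso",
   "offset_xyz": [
    0.42,
    0.0,
    0.05
   ]
  },
  {
   "name": "tail_base_m",
   "link": "tail_base",
   "offset_xyz": [
    0.0,
    0.0,
    0.0
   ]
  },
  {
   "name": "tail_mid",
   "link": "tail_base",
   "offset_xyz": [
    0.3,
    0.0,
    0.0
   ]
  },
  {
   "name": "tail_tip_m",
   "link": "tail_tip",
   "offset_xyz": [
    0.3,
    0.0,
    0.0
   ]
  },
  {
   "name": "lf_top",
   "link": "lf_upper",
   "offset_xyz": [
    0.0,
    0.0,
    0.0
   ]
  },
  {
   "name": "lf_knee",
   "link": "lf_upper",
   "offset_xyz": [
    0.0,
    0.0,
    -0.26
   ]
  },
  {
   "name": "lf_ankle",
   "link": "lf_lower",
   "offset_xyz": [
    0.0,
    0.0,
    -0.24
   ]
  },
  {
   "name": "lf_paw_m",
   "link": "lf_paw",
   "offset_xyz": [
    0.0,
    0.0,
    -0.1
   ]
  },
  {
   "name": "rf_top",
   "link": "rf_upper",
   "offset_xyz": [
    0.0,
    0.0,
    0.0
   ]
  },
  {
   "name": "rf_knee",
   "link": "rf_upper",
   "offset_xyz": [
    0.0,
    0.0,
    -0.26
   ]
  },
  {
   "name": "rf_ankle",
   "link": "rf_lower",
   "offset_xyz": [
    0.0,
    0.0,
    -0.24
   ]
  },
  {
   "name": "rf_paw_m",
   "link": "rf_paw",
   "offset_xyz": [
    0.0,
    0.0,
    -0.1
   ]
  },
  {
   "name": "lh_top",
   "link": "lh_upper",
   "offset_xyz": [
    0.0,
    0.0,
    0.0
   ]
  },
  {
   "name": "lh_knee",
   "link": "lh_upper",
   "offset_xyz": [
    0.0,
    0.0,
    -0.3
   ]
  },
  {
   "name": "lh_ankle",
   "link": "lh_lower",
   "offset_xyz": [
    0.0,
    0.0,
    -0.28
   ]
  },
  {
   "name": "lh_paw_m",
   "link": "lh_paw",
   "offset_xyz": [
    0.0,
    0.0,
    -0.12
   ]
  },
  {
   "name": "rh_top",
   "link": "rh_upper",
   "offset_xyz": [
    0.0,
    0.0,
    0.0
   ]
  },
  {
   "name": "rh_knee",
   "link": "rh_upper",
   "offset_xyz": [
    0.0,
    0.0,
    -0.3
   ]
  },
  {
   "name": "rh_ankle",
   "link": "rh_lower",
   "offset_xyz": [
    0.0,
    0.0,
    -0.28
   ]
  },
  {
   "name": "rh_paw_m",
   "link": "rh_paw",
   "offset_xyz": [
    0.0,
    0.0,
    -0.12
   ]
  }
 ],
 "gravity": 9.81
}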