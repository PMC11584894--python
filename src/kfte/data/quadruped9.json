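{
 "links": [
  {
   "name": "torso",
   "parent": null,
   "length": 0.6,
   "mass": 20.0,
   "radius": 0.08,
   "offset": 0.0,
   "axis": [
    1.0,
    0.0,
    0.0
   ]
  },
  {
   "name": "lf_upper",
   "parent": "torso",
   "length": 0.28,
   "mass": 1.6,
   "radius": 0.04,
   "offset": [
    0.6,
    0.1,
    0.0
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
   "length": 0.26,
   "mass": 0.6,
   "radius": 0.03,
   "offset": 0.28,
   "axis": [
    0.0,
    0.0,
    -1.0
   ]
  },
  {
   "name": "rf_upper",
   "parent": "torso",
   "length": 0.28,
   "mass": 1.6,
   "radius": 0.04,
   "offset": [
    0.6,
    -0.1,
    0.0
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
   "length": 0.26,
   "mass": 0.6,
   "radius": 0.03,
   "offset": 0.28,
   "axis": [
    0.0,
    0.0,
    -1.0
   ]
  },
  {
   "name": "lh_upper",
   "parent": "torso",
   "length": 0.28,
   "mass": 1.6,
   "radius": 0.04,
   "offset": [
    0.0,
    0.1,
    0.0
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
   "length": 0.26,
   "mass": 0.6,
   "radius": 0.03,
   "offset": 0.28,
   "axis": [
    0.0,
    0.0,
    -1.0
   ]
  },
  {
   "name": "rh_upper",
   "parent": "torso",
   "length": 0.28,
   "mass": 1.6,
   "radius": 0.04,
   "offset": [
    0.0,
    -0.1,
    0.0
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
   "length": 0.26,
   "mass": 0.6,
   "radius": 0.03,
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
   "kind": "spherical",
   "i": "torso",
   "j": "lf_upper"
  },
  {
   "kind": "revolute",
   "i": "lf_upper",
   "j": "lf_lower"
  },
  {
   "kind": "spherical",
   "i": "torso",
   "j": "rf_upper"
  },
  {
   "kind": "revolute",
   "i": "rf_upper",
   "j": "rf_lower"
  },
  {
   "kind": "spherical",
   "i": "torso",
   "j": "lh_upper"
  },
  {
   "kind": "revolute",
   "i": "lh_upper",
   "j": "lh_lower"
  },
  {
   "kind": "spherical",
   "i": "torso",
   "j": "rh_upper"
  },
  {
   "kind": "revolute",
   "i": "rh_upper",
   "j": "rh_lower"
  }
 ],
 "markers": [
  {
   "name": "pelvis",
   "link": "torso",
   "offset_xyz": [
    0.0,
    0.0,
    0.02
   ]
  },
  {
   "name": "spine_mid",
   "link": "torso",
   "offset_xyz": [
    0.3,
    0.0,
    0.04
   ]
  },
  {
   "name": "withers",
   "link": "torso",
   "offset_xyz": [
    0.6,
    0.0,
    0.03
   ]
  },
  {
   "name": "nose",
   "link": "torso",
   "offset_xyz": [
    0.72,
    0.0,
    0.1
   ]
  },
  {
   "name": "left_eye",
   "link": "torso",
   "offset_xyz": [
    0.68,
    0.03,
    0.14
   ]
  },
  {
   "name": "lf_knee",
   "link": "lf_upper",
   "offset_xyz": [
    0.0,
    0.0,
    -0.28
   ]
  },
  {
   "name": "lf_shank",
   "link": "lf_lower",
   "offset_xyz": [
    0.0,
    0.0,
    -0.13
   ]
  },
  {
   "name": "lf_foot",
   "link": "lf_lower",
   "offset_xyz": [
    0.0,
    0.0,
    -0.26
   ]
  },
  {
   "name": "rf_knee",
   "link": "rf_upper",
   "offset_xyz": [
    0.0,
    0.0,
    -0.28
   ]
  },
  {
   "name": "rf_shank",
   "link": "rf_lower",
   "offset_xyz": [
    0.0,
    0.0,
    -0.13
   ]
  },
  {
   "name": "rf_foot",
   "link": "rf_lower",
   "offset_xyz": [
    0.0,
    0.0,
    -0.26
   ]
  },
  {
   "name": "lh_knee",
   "link": "lh_upper",
   "offset_xyz": [
    0.0,
    0.0,
    -0.28
   ]
  },
  {
   "name": "lh_shank",
   "link": "lh_lower",
   "offset_xyz": [
    0.0,
    0.0,
    -0.13
   ]
  },
  {
   "name": "lh_foot",
   "link": "lh_lower",
   "offset_xyz": [
    0.0,
    0.0,
    -0.26
   ]
  },
  {
   "name": "rh_knee",
   "link": "rh_upper",
   "offset_xyz": [
    0.0,
    0.0,
    -0.28
   ]
  },
  {
   "name": "rh_shank",
   "link": "rh_lower",
   "offset_xyz": [
    0.0,
    0.0,
    -0.13
   ]
  },
  {
   "name": "rh_foot",
   "link": "rh_lower",
   "offset_xyz": [
    0.0,
    0.0,
    -0.26
   ]
  }
 ],
 "gravity": 9.81
}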