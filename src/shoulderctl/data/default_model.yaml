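# Reference right-arm model: driver-like posture, humerus horizontal forward,
# elbow locked at 130 degrees. World frame: X forward, Y lateral (subject's
# right), Z up. Units: m, kg, s, N, deg; PCSA in cm^2.
#
# The glenohumeral joint sits at world (-0.03, 0.18, 0.0); segment-local
# coordinates below are expressed in each segment's own frame (torso frame
# coincides with world; scapula/humerus/forearm frames originate at their
# parent joints).

model:
  elbow_angle_deg: 130.0
  gravity: 9.81
  gravity_compensation: true
  integrator: semi_implicit
  dt: 0.001
  hill:
    fl_width: 0.45
    a_rel: 0.25
    v_max: 10.0
    fv_ecc_plateau: 1.5
    passive_scale: 0.01
    passive_rate: 8.0
    damping: 0.1

  segments:
    - {name: torso, mass: 30.0, inertia: [1.0, 1.0, 1.0], com_offset: [0.0, 0.0, -0.2]}
    - {name: scapula, mass: 0.8, inertia: [0.002, 0.002, 0.002], com_offset: [-0.03, 0.02, 0.0]}
    - {name: humerus, mass: 2.1, inertia: [0.002, 0.015, 0.015], com_offset: [0.13, 0.0, 0.0]}
    - {name: forearm, mass: 1.9, inertia: [0.0015, 0.02, 0.02], com_offset: [0.12, 0.0, 0.0]}

  joints:
    # scapulothoracic glide: planar translation (protraction X, elevation Z)
    # with elastic centering standing in for the scapula-torso contact.
    - name: scapulothoracic
      kind: planar_2dof
      parent: torso
      child: scapula
      parent_anchor: [-0.03, 0.14, 0.0]
      axes: [[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]]
      rotation_limits: [[-0.04, 0.04], [-0.04, 0.04]]
      stop_stiffness: 20000.0
      stop_damping: 200.0
      centering_stiffness: 4000.0
      centering_damping: 60.0
      viscous_damping: 20.0
    # glenohumeral ball joint; the tight lower adduction range on the third
    # axis models the arm contacting the torso.  The elastic centering is a
    # lumped surrogate for the capsule and ligaments of the passive joint.
    - name: glenohumeral
      kind: spherical_3dof
      parent: scapula
      child: humerus
      parent_anchor: [0.0, 0.04, 0.0]
      rotation_limits: [[-0.8, 0.8], [-1.0, 1.0], [-0.35, 1.0]]
      stop_stiffness: 60.0
      stop_damping: 5.0
      viscous_damping: 0.8
      centering_stiffness: 65.0
      centering_damping: 1.5
    # elbow locked at the configured included angle (50 deg off straight,
    # forearm pointing forward-medial).
    - name: elbow
      kind: locked
      parent: humerus
      child: forearm
      parent_anchor: [0.31, 0.0, 0.0]
      locked_axis: [0.0, 0.0, 1.0]
      locked_angle_deg: -50.0

  muscles:
    # --- glenohumeral (APF) muscles -----------------------------------
    - name: ant_deltoid
      action_phi_deg: 124.0
      pcsa: 5.0
      controller_assignment: apf
      path:
        - {segment: torso, point: [0.03, 0.15, 0.05]}
        - {segment: humerus, point: [0.12, 0.01, 0.01]}
    - name: mid_deltoid
      action_phi_deg: 20.0
      pcsa: 13.0
      controller_assignment: apf
      path:
        - {segment: scapula, point: [0.0, 0.09, 0.02]}
        - {segment: humerus, point: [0.12, 0.01, 0.0]}
    - name: post_deltoid
      action_phi_deg: 297.0
      pcsa: 9.0
      controller_assignment: apf
      path:
        - {segment: scapula, point: [-0.06, 0.055, -0.03]}
        - {segment: humerus, point: [0.12, 0.0, -0.005]}
    - name: pect_major_clav
      action_phi_deg: 171.0
      pcsa: 1.5
      controller_assignment: apf
      path:
        - {segment: torso, point: [0.05, 0.06, 0.02]}
        - {segment: humerus, point: [0.10, 0.0, 0.01]}
    - name: pect_major_stern
      action_phi_deg: 208.0
      pcsa: 1.5
      controller_assignment: apf
      path:
        - {segment: torso, point: [0.05, 0.02, -0.06]}
        - {segment: humerus, point: [0.10, 0.0, 0.0]}
    - name: latissimus_dorsi
      action_phi_deg: 239.0
      pcsa: 2.2
      controller_assignment: apf
      path:
        - {segment: torso, point: [-0.08, 0.0, -0.18]}
        - {segment: humerus, point: [0.08, 0.0, -0.01]}
    - name: infraspinatus
      action_phi_deg: 155.0
      pcsa: 2.2
      controller_assignment: apf
      path:
        - {segment: scapula, point: [-0.07, -0.02, -0.005]}
        - {segment: humerus, point: [0.05, 0.02, 0.015]}
    # bi-articular muscles: half the PCSA drives the shoulder controller
    - name: biceps_brachii
      action_phi_deg: 91.0
      pcsa: 5.0
      shoulder_fraction: 0.5
      controller_assignment: apf
      path:
        - {segment: scapula, point: [0.005, 0.04, 0.02]}
        - {segment: humerus, point: [0.05, 0.0, 0.025]}
        - {segment: forearm, point: [0.04, 0.0, 0.01]}
    - name: triceps_brachii
      action_phi_deg: 251.0
      pcsa: 13.0
      shoulder_fraction: 0.5
      controller_assignment: apf
      path:
        - {segment: scapula, point: [0.005, 0.035, -0.015]}
        - {segment: humerus, point: [0.15, 0.0, -0.02]}
        - {segment: forearm, point: [-0.02, 0.005, 0.0]}
    # --- scapular (MLF) muscles ---------------------------------------
    - name: upper_trapezius
      pcsa: 8.0
      controller_assignment: mlf
      path:
        - {segment: torso, point: [-0.02, 0.0, 0.12]}
        - {segment: scapula, point: [0.01, 0.07, 0.03]}
    - name: middle_trapezius
      pcsa: 6.0
      controller_assignment: mlf
      path:
        - {segment: torso, point: [-0.07, 0.0, 0.03]}
        - {segment: scapula, point: [-0.05, 0.01, 0.02]}
    - name: lower_trapezius
      pcsa: 6.0
      controller_assignment: mlf
      path:
        - {segment: torso, point: [-0.09, 0.0, -0.10]}
        - {segment: scapula, point: [-0.05, 0.0, 0.0]}
    # serratus wraps the ribcage: series chain of two elements via a rib point
    - name: serratus_anterior
      pcsa: 10.0
      controller_assignment: mlf
      path:
        - {segment: torso, point: [0.06, 0.08, -0.05]}
        - {segment: torso, point: [0.01, 0.12, -0.03]}
        - {segment: scapula, point: [-0.05, 0.0, -0.02]}
    - name: rhomboid_major
      pcsa: 5.0
      controller_assignment: mlf
      path:
        - {segment: torso, point: [-0.09, 0.0, 0.01]}
        - {segment: scapula, point: [-0.06, 0.0, 0.0]}
    - name: levator_scapulae
      pcsa: 4.0
      controller_assignment: mlf
      path:
        - {segment: torso, point: [-0.04, 0.02, 0.14]}
        - {segment: scapula, point: [-0.02, 0.02, 0.04]}

controller:
  apf_delay_ms: 30.0
  mlf_delay_ms: 10.0
  tau_act_ms: 15.0
  tau_deact_ms: 40.0
  mlf_baseline: 0.01
  frame_mode: ground
  gains:
    p_apf: 1.6
    d_apf: 150.0
    p_mlf: 0.5
    d_mlf: 5.0
    label: Baseline

experiment:
  drop_mass: 8.0
  initial_mass_velocity: 0.77
  routing_distance: 1.5
  duration: 1.0
  attachment:
    segment: forearm
    point: [0.0, 0.0, 0.0]

evaluation:
  window_ms: 800.0
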