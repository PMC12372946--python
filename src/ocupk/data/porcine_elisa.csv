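group,analyte,compartment,time_h,mean,sd,n
topical_cpp,RBZ,Aq,0.3333333333333333,6.76e-3,1.17e-2,3
topical_cpp,RBZ,Aq,0.6666666666666666,3.80e-2,6.58e-2,3
topical_cpp,RBZ,Aq,1.0,0.0,0.0,3
topical_cpp,RBZ,Aq,3.5,7.14e-2,9.46e-2,3
topical_cpp,RBZ,Vit,0.3333333333333333,3.66e-2,1.11e-2,3
topical_cpp,RBZ,Vit,0.6666666666666666,8.79e-2,1.80e-2,3
topical_cpp,RBZ,Vit,1.0,0.187,9.94e-2,3
topical_cpp,RBZ,Vit,3.5,0.364,0.189,3
topical_cpp,VEGF,Aq,0.3333333333333333,8.01e-3,4.52e-4,3
topical_cpp,VEGF,Aq,0.6666666666666666,8.08e-3,1.50e-3,3
topical_cpp,VEGF,Aq,1.0,8.85e-3,6.06e-4,3
topical_cpp,VEGF,Aq,3.5,6.26e-4,1.08e-3,3
topical_cpp,VEGF,Vit,0.3333333333333333,7.34e-3,1.55e-3,3
topical_cpp,VEGF,Vit,0.6666666666666666,6.59e-3,1.25e-3,3
topical_cpp,VEGF,Vit,1.0,5.09e-3,1.59e-3,3
topical_cpp,VEGF,Vit,3.5,7.47e-3,1.26e-3,3
invit_cpp,RBZ,Aq,0.3333333333333333,1.39e-2,0.196,3
invit_cpp,RBZ,Aq,0.6666666666666666,3.12e-2,5.41e-2,3
invit_cpp,RBZ,Aq,1.0,2.00e-2,2.83e-2,3
invit_cpp,RBZ,Aq,3.5,2.63,1.94,3
invit_cpp,RBZ,Vit,0.3333333333333333,1.30,0.384,3
invit_cpp,RBZ,Vit,0.6666666666666666,2.41,1.29,3
invit_cpp,RBZ,Vit,1.0,2.91,0.101,3
invit_cpp,RBZ,Vit,3.5,4.40,4.40e-2,3
invit_cpp,VEGF,Aq,0.3333333333333333,9.20e-3,5.11e-4,3
invit_cpp,VEGF,Aq,0.6666666666666666,9.53e-3,4.32e-4,3
invit_cpp,VEGF,Aq,1.0,1.60e-2,1.10e-2,3
invit_cpp,VEGF,Aq,3.5,6.51e-3,6.05e-3,3
invit_cpp,VEGF,Vit,0.3333333333333333,2.84e-3,4.02e-3,3
invit_cpp,VEGF,Vit,0.6666666666666666,2.11e-3,1.67e-3,3
invit_cpp,VEGF,Vit,1.0,1.36e-3,1.23e-3,3
invit_cpp,VEGF,Vit,3.5,5.01e-5,8.68e-5,3
invit_plain,RBZ,Aq,0.3333333333333333,4.73e-2,0.0,3
invit_plain,RBZ,Aq,0.6666666666666666,4.27e-2,7.40e-2,3
invit_plain,RBZ,Aq,1.0,0.774,0.931,3
invit_plain,RBZ,Aq,3.5,4.35,1.86e-2,3
invit_plain,RBZ,Vit,0.3333333333333333,4.29,0.435,3
invit_plain,RBZ,Vit,0.6666666666666666,3.73,0.186,3
invit_plain,RBZ,Vit,1.0,4.11,0.312,3
invit_plain,RBZ,Vit,3.5,4.47,0.236,3
invit_plain,VEGF,Aq,0.3333333333333333,8.25e-3,1.96e-3,3
invit_plain,VEGF,Aq,0.6666666666666666,1.23e-2,6.35e-4,3
invit_plain,VEGF,Aq,1.0,7.84e-3,4.31e-3,3
invit_plain,VEGF,Aq,3.5,6.52e-3,5.84e-3,3
invit_plain,VEGF,Vit,0.3333333333333333,6.73e-3,3.02e-3,3
invit_plain,VEGF,Vit,0.6666666666666666,0.0,0.0,3
invit_plain,VEGF,Vit,1.0,0.0,0.0,3
invit_plain,VEGF,Vit,3.5,0.0,0.0,3
control,RBZ,Aq,,0.0,0.0,3
control,RBZ,Vit,,0.348,0.459,3
control,VEGF,Aq,,9.87e-3,1.24e-3,3
control,VEGF,Vit,,0.0,0.0,3
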