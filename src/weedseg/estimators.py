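"""scikit-learn style estimators wrapping the segmentation pipeline.

:class:`WeedSegmenter` is a fit/predict estimator over (image, mask)
arrays that trains the improved UNet with the two-phase freeze/unfreeze
regime; :class:`BroadleafExtractor` is a stateless transformer applying
the morphological post-processor to (image, predicted mask) pairs. Both
follow the sklearn contract (``get_params``/``set_params``, fitted
attributes with trailing underscores, ``check_is_fitted``-compatible),
so they compose with sklearn model selection and pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .broadleaf import StructuringElement, extract_broadleaf
from .metrics import confusion, miou
from .training import TrainConfig, train
from .unet import ImprovedUNet, segment_image


def _as_image_list(X):
    imgs = [np.asarray(x) for x in X]
    for i, im in enumerate(imgs):
        if im.ndim != 3 or im.shape[2] != 3:
            raise ValueError(f"sample {i}: expected H x W x 3 image, got {im.shape}")
        if im.shape[0] % 32 or im.shape[1] % 32:
            raise ValueError(
                f"sample {i}: size {im.shape[:2]} must be divisible by 32")
    return imgs


class WeedSegmenter(BaseEstimator):
    """Soybean/grass semantic segmenter (SE-ResNet34 improved UNet).

    Parameters
    ----------
    use_se : bool
        Embed squeeze-excitation attention in every encoder block.
    enable_fusion : bool
        Concatenate the five restored shallow encoder taps into the
        final prediction map.
    se_reduction, fusion_channels : int
        SE bottleneck ratio and per-tap fused channel width.
    epochs, freeze_epochs, batch_size, lr_init, lr_min, beta1 :
        Training regime; defaults are the reference field protocol
        (500 epochs, first 50 with the encoder frozen, batch 8, cosine
        0.01 -> 0.001, Adam). Scale epochs down for desk-size runs.
    seed : int
        Governs weight init and batch shuffling.

    Attributes
    ----------
    model_ : ImprovedUNet          — the trained network.
    log_ : TrainLog                — per-epoch loss/lr/accuracy records.
    classes_ : ndarray             — the predicted class indices [0, 1, 2].
    """

    def __init__(self, use_se=True, enable_fusion=True, se_reduction=16,
                 fusion_channels=16, epochs=500, freeze_epochs=50, batch_size=8,
                 lr_init=0.01, lr_min=0.001, beta1=0.9, seed=0):
        self.use_se = use_se
        self.enable_fusion = enable_fusion
        self.se_reduction = se_reduction
        self.fusion_channels = fusion_channels
        self.epochs = epochs
        self.freeze_epochs = freeze_epochs
        self.batch_size = batch_size
        self.lr_init = lr_init
        self.lr_min = lr_min
        self.beta1 = beta1
        self.seed = seed

    def _build(self):
        return ImprovedUNet(use_se=self.use_se, enable_fusion=self.enable_fusion,
                            se_reduction=self.se_reduction,
                            fusion_channels=self.fusion_channels, seed=self.seed)

    def fit(self, X, y, val_pairs=None, stop_accuracy=None):
        """Train on images X and label masks y (values in {0, 1, 2})."""
        imgs = _as_image_list(X)
        masks = [np.asarray(m) for m in y]
        if len(imgs) != len(masks):
            raise ValueError("X and y lengths differ")
        for i, (im, m) in enumerate(zip(imgs, masks)):
            if im.shape[:2] != m.shape:
                raise ValueError(f"sample {i}: image/mask size mismatch")
        cfg = TrainConfig(epochs=self.epochs, freeze_epochs=self.freeze_epochs,
                          batch_size=self.batch_size, lr_init=self.lr_init,
                          lr_min=self.lr_min, beta1=self.beta1, seed=self.seed)
        self.model_ = self._build()
        self.model_, self.log_ = train(self.model_, list(zip(imgs, masks)), cfg,
                                       val_pairs=val_pairs,
                                       stop_accuracy=stop_accuracy)
        self.classes_ = np.array([0, 1, 2])
        return self

    def predict(self, X):
        """Predict an H x W class mask for every image."""
        if not hasattr(self, "model_"):
            raise AttributeError("WeedSegmenter is not fitted yet; call fit first")
        return [segment_image(self.model_, im) for im in _as_image_list(X)]

    def score(self, X, y):
        """Mean IoU of the predictions against the reference masks."""
        cm = np.zeros((3, 3), dtype=np.int64)
        for pred, truth in zip(self.predict(X), y):
            cm += confusion(pred, np.asarray(truth), 3)
        return miou(cm)


class BroadleafExtractor(BaseEstimator, TransformerMixin):
    """Morphological broadleaf recovery as a stateless transformer.

    ``transform`` maps (image, predicted 3-class mask) pairs to final
    four-class masks: vegetation pixels not explained by the predicted
    soybean or (dilated) grass regions, surviving the connected-component
    area filter, become broadleaf.
    """

    def __init__(self, dilate_size=5, dilate_shape="square", min_area=64):
        self.dilate_size = dilate_size
        self.dilate_shape = dilate_shape
        self.min_area = min_area

    def fit(self, X=None, y=None):
        self.se_ = StructuringElement(self.dilate_shape, self.dilate_size)
        return self

    def transform(self, X):
        if not hasattr(self, "se_"):
            self.fit()
        return [extract_broadleaf(img, pred, se=self.se_, min_area=self.min_area)
                for img, pred in X]
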